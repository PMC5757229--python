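"""Treatment effect: mapping LDL-C lowering to per-event rate reductions.

The intervention's observed relative LDL-C reduction is converted to an
absolute reduction in mmol/L and applied through event-specific rate ratios
per 1 mmol/L: the rate of an event after treatment is
``base_rate * RR ** delta_LDL(mmol/L)``.  No effect is applied to heart
failure, to IS death (ratio fixed at 1), or to revascularisation incident on
acute MI (that pathway is mediated by the reduced MI incidence itself).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple, Union

import pandas as pd

from .inputs import MGDL_PER_MMOL, InputError
from .states import Event, HealthState, Kind


@dataclass
class EfficacyInputs:
    """Trial-derived efficacy and effectiveness inputs.

    ``ldl_reduction_pct`` is the relative LDL-C reduction versus control
    (0.6131 = 61.31%); the ``prop_effective_*`` fields are the proportions of
    patients attaining a >=50% LDL-C reduction on each arm, which weight
    survival into effectively treated patient-years.
    """

    ldl_reduction_pct: float = 0.6131
    ldl_reduction_ci: Tuple[float, float] = (0.5782, 0.6480)
    prop_effective_treatment: float = 0.7925
    prop_effective_treatment_ci: Tuple[float, float] = (0.7028, 0.8651)
    prop_effective_control: float = 0.0196
    prop_effective_control_ci: Tuple[float, float] = (0.0005, 0.1045)
    baseline_ldl_mgdl: float = 155.46
    mgdl_per_mmol: float = MGDL_PER_MMOL

    def validate(self) -> "EfficacyInputs":
        for name in (
            "ldl_reduction_pct",
            "prop_effective_treatment",
            "prop_effective_control",
        ):
            v = getattr(self, name)
            lo, hi = getattr(self, name.replace("_pct", "") + "_ci") if name.endswith(
                "_pct"
            ) else getattr(self, name + "_ci")
            if not 0.0 <= v <= 1.0:
                raise InputError(f"EfficacyInputs: {name} = {v} outside [0, 1]")
            if not lo <= v <= hi:
                raise InputError(f"EfficacyInputs: {name} outside its CI ({lo}, {hi})")
        if self.baseline_ldl_mgdl <= 0 or self.mgdl_per_mmol <= 0:
            raise InputError("EfficacyInputs: LDL scale inputs must be positive")
        return self

    def prop_effective(self, arm: str) -> float:
        if arm == "treatment":
            return self.prop_effective_treatment
        if arm == "control":
            return self.prop_effective_control
        raise InputError(f"unknown arm {arm!r}")


def delta_ldl_mmol(eff: EfficacyInputs) -> float:
    """Absolute LDL-C reduction in mmol/L implied by the relative reduction
    applied at the cohort's baseline level."""
    return eff.ldl_reduction_pct * eff.baseline_ldl_mgdl / eff.mgdl_per_mmol


@dataclass
class RateRatio:
    rr: float
    ci: Tuple[float, float] = (None, None)
    ci_level: float = 0.99
    fixed: bool = False

    def validate(self, name: str) -> "RateRatio":
        if self.rr <= 0:
            raise InputError(f"RateRatioTable: {name} rate ratio must be positive")
        return self


#: Events carrying a treatment-effect rate ratio (revascularisation is a
#: procedure, not a state transition).
RR_EVENTS = ("ecvd", "mi", "is", "chd_death", "is_death", "revascularisation")


def _default_ratios() -> Dict[str, RateRatio]:
    return {
        "ecvd": RateRatio(0.71, (0.58, 0.87), 0.99),  # assumed equivalent to MI
        "mi": RateRatio(0.71, (0.58, 0.87), 0.99),
        "is": RateRatio(0.69, (0.50, 0.95), 0.99),
        "chd_death": RateRatio(0.80, (0.76, 0.85), 0.99),
        "is_death": RateRatio(1.00, (1.00, 1.00), 0.95, fixed=True),
        "revascularisation": RateRatio(0.66, (0.60, 0.73), 0.95),
    }


@dataclass
class RateRatioTable:
    """Per-event rate ratios per 1 mmol/L of LDL-C reduction.

    Defaults are the meta-analytic statin estimates: MI 0.71, IS 0.69,
    CHD death 0.80 (99% CIs), revascularisation 0.66 (95% CI); IS death is
    fixed at 1 for lack of a statistically significant effect; the ECVD row
    is assumed equivalent to MI.
    """

    ratios: Dict[str, RateRatio] = field(default_factory=_default_ratios)

    def validate(self) -> "RateRatioTable":
        for name in RR_EVENTS:
            if name not in self.ratios:
                raise InputError(f"RateRatioTable: missing event {name}")
            self.ratios[name].validate(name)
        if self.ratios["is_death"].rr != 1.0:
            raise InputError("RateRatioTable: the IS-death ratio is fixed at 1")
        return self

    def __getitem__(self, event: str) -> RateRatio:
        try:
            return self.ratios[event]
        except KeyError:
            raise InputError(f"RateRatioTable: unknown event {event!r}")

    # -- IO ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event": name,
                    "rr": r.rr,
                    "ci_lo": r.ci[0],
                    "ci_hi": r.ci[1],
                    "ci_level": r.ci_level,
                    "fixed": r.fixed,
                }
                for name, r in self.ratios.items()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateRatioTable":
        frame = pd.read_csv(path)
        ratios = {
            rec["event"]: RateRatio(
                float(rec["rr"]),
                (float(rec["ci_lo"]), float(rec["ci_hi"])),
                float(rec["ci_level"]),
                bool(rec.get("fixed", False)),
            )
            for rec in frame.to_dict(orient="records")
        }
        return cls(ratios).validate()


def treated_rate(base_rate: float, rr_per_mmol: float, delta: float) -> float:
    """Event rate after an LDL-C reduction of ``delta`` mmol/L:
    ``base_rate * rr_per_mmol ** delta``."""
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    if rr_per_mmol <= 0:
        raise ValueError("rate ratio must be positive")
    if delta < 0:
        raise ValueError("LDL-C reduction must be non-negative")
    return base_rate * rr_per_mmol**delta


def effect_applies(event: Union[Event, str], context=None) -> bool:
    """Whether the treatment effect applies to an event in a given context.

    Heart failure carries no effect; IS death is fixed at ratio 1; and the
    revascularisation effect applies to ECVD and post-MI occupancy but not to
    acute-MI patients (mediated by reduced MI incidence).  ``context`` is a
    :class:`~etpymodel.states.HealthState` (or its kind) and only matters for
    revascularisation.
    """
    name = event.value if isinstance(event, Event) else str(event)
    if name in ("hf", "is_death"):
        return False
    if name in ("mi", "is", "chd_death", "ecvd"):
        return True
    if name == "revascularisation":
        kind = context.kind if isinstance(context, HealthState) else context
        if kind in (Kind.ACUTE_MI, "acute_mi"):
            return False
        return True
    raise InputError(f"effect_applies: unknown event {name!r}")


def event_multipliers(
    table: RateRatioTable, delta: float, on_treatment: bool
) -> Dict[str, float]:
    """Per-event rate multipliers ``RR ** delta`` for one arm.

    Keys ``mi``/``is``/``hf``/``chd_death``/``is_death`` multiply event
    rates; ``revasc_chronic`` applies to ECVD/post-MI revascularisation and
    ``revasc_acute_mi`` is always 1.
    """
    if not on_treatment or delta == 0.0:
        return {
            "mi": 1.0,
            "is": 1.0,
            "hf": 1.0,
            "chd_death": 1.0,
            "is_death": 1.0,
            "revasc_chronic": 1.0,
            "revasc_acute_mi": 1.0,
        }
    return {
        "mi": table["mi"].rr ** delta,
        "is": table["is"].rr ** delta,
        "hf": 1.0,  # no effect on heart failure
        "chd_death": table["chd_death"].rr ** delta,
        "is_death": 1.0,  # ratio fixed at 1
        "revasc_chronic": table["revascularisation"].rr ** delta,
        "revasc_acute_mi": 1.0,  # mediated by reduced MI incidence
    }
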