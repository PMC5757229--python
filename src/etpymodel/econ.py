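"""Cost and outcome accumulation: life-years, ETPYs, events, costs, ICER.

Effectively treated patient-years (ETPYs) weight each cycle's survival by the
proportion of patients attaining a >=50% LDL-C reduction on that arm, so the
outcome combines length of life with attainment of the guideline lipid
target.  The incremental cost-effectiveness ratio is incremental cost per
incremental ETPY.

Discounting convention: the first cycle is undiscounted and cycle t carries
the factor ``1 / (1 + r) ** (t - 1)``, applied to trapezoid-averaged
within-cycle quantities.  Acute, fatal and revascularisation costs attach to
incidence; post-event costs to chronic-state occupancy (composites at the
highest member cost); drug costs to alive person-time.  Event counts are
reported undiscounted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .effect import EfficacyInputs
from .inputs import InputError
from .markov import CohortTrace
from .states import EVENT_ORDER, Event

COST_CATEGORIES = (
    "medication",
    "non_fatal_acute",
    "fatal",
    "revascularisation",
    "post_event",
)


def _default_acute_costs() -> Dict[str, float]:
    # Acute (year 1) direct costs per event, BGN (2015).
    return {
        "mi": 7384.10,
        "is": 4154.84,
        "hf": 2569.28,
        "chd_death": 5171.50,
        "is_death": 8095.00,
        "revascularisation": 5498.92,
    }


def _default_post_costs() -> Dict[str, float]:
    # Post-event annual costs, BGN; ECVD assumed equal to post-MI.
    return {
        "ecvd": 582.05,
        "post_mi": 582.05,
        "post_is": 223.03,
        "post_hf": 2564.61,
    }


@dataclass
class CostTable:
    """Direct cost inputs in BGN (2015, payer perspective).

    The CHD-death and revascularisation unit costs are mixtures (fatal
    unstable angina / fatal MI / fatal HF, and PCI / CABG); the mixture
    metadata is stored for audit alongside the blended values used in the
    model.  ``drug_annual`` holds annual drug acquisition costs per arm
    component; the packaged values are synthetic stand-ins for unpublished
    list prices.
    """

    acute: Dict[str, float] = field(default_factory=_default_acute_costs)
    post: Dict[str, float] = field(default_factory=_default_post_costs)
    chd_death_mixture: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "fatal_ua": {"share": 0.283, "cost": 5270.00},
            "fatal_mi": {"share": 0.566, "cost": 6380.00},
            "fatal_hf": {"share": 0.150, "cost": 420.00},
        }
    )
    revasc_mixture: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "pci": {"share": 0.785, "cost": 4238.00},
            "cabg": {"share": 0.215, "cost": 10100.00},
        }
    )
    drug_annual: Dict[str, float] = field(
        default_factory=lambda: {"evolocumab": 10650.0, "statin": 128.0}
    )

    def validate(self) -> "CostTable":
        for group in (self.acute, self.post, self.drug_annual):
            for k, v in group.items():
                if v < 0:
                    raise InputError(f"CostTable: negative cost for {k}")
        for name, mixture in (
            ("chd_death_mixture", self.chd_death_mixture),
            ("revasc_mixture", self.revasc_mixture),
        ):
            total = sum(c["share"] for c in mixture.values())
            if abs(total - 1.0) > 0.005:
                raise InputError(f"CostTable: {name} shares sum to {total:.4f}")
        return self

    def arm_drug_cost(self, arm: str) -> float:
        if arm == "treatment":
            return self.drug_annual["evolocumab"] + self.drug_annual["statin"]
        if arm == "control":
            return self.drug_annual["statin"]
        raise InputError(f"CostTable: no drug cost defined for arm {arm!r}")

    def post_cost_for_memory(self, memory) -> float:
        """Annual post-event cost of a chronic state: highest member cost."""
        return max(self.post[f.value] for f in memory)


@dataclass
class DiscountSpec:
    """Annual discount rates; mid-cycle quantities via the trapezoid rule."""

    rate_costs: float = 0.05
    rate_outcomes: float = 0.05

    def validate(self) -> "DiscountSpec":
        if self.rate_costs < 0 or self.rate_outcomes < 0:
            raise InputError("DiscountSpec: discount rates must be non-negative")
        return self


def discount_factor(cycle: int, rate: float) -> float:
    """Discount factor for cycle t (1-based): ``1 / (1 + r) ** (t - 1)``.

    The first cycle is undiscounted under this convention.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    return (1.0 + rate) ** (-(cycle - 1))


def _discount_vector(n: int, rate: float) -> np.ndarray:
    return (1.0 + rate) ** (-np.arange(n, dtype=float))


@dataclass
class ArmResults:
    """Per-arm accumulated outcomes and costs (per modelled patient)."""

    arm: str
    ly: float
    etpy: float
    events: Dict[str, float]
    costs: Dict[str, float]

    @property
    def total_cost(self) -> float:
        return self.costs["total"]

    def validate(self) -> "ArmResults":
        if self.etpy > self.ly + 1e-9:
            raise InputError("ArmResults: etpy exceeds life-years")
        if any(v < 0 for v in self.events.values()):
            raise InputError("ArmResults: negative event count")
        if any(v < -1e-9 for v in self.costs.values()):
            raise InputError("ArmResults: negative cost")
        cat_sum = sum(self.costs[c] for c in COST_CATEGORIES)
        if abs(cat_sum - self.costs["total"]) > 1e-6:
            raise InputError("ArmResults: cost categories do not sum to total")
        return self


def accumulate_outcomes(
    trace: CohortTrace,
    eff: EfficacyInputs,
    costs: CostTable,
    disc: DiscountSpec,
    arm: str,
    *,
    drug_cost_per_cycle: Optional[Sequence[float]] = None,
    prop_effective_per_cycle: Optional[Sequence[float]] = None,
) -> ArmResults:
    """Accumulate discounted life-years, ETPYs, events and costs for one arm.

    ``drug_cost_per_cycle`` / ``prop_effective_per_cycle`` override the
    constant arm values (used for finite treatment-duration scenarios).
    """
    disc.validate()
    costs.validate()
    T = trace.n_cycles
    df_out = _discount_vector(T, disc.rate_outcomes)
    df_cost = _discount_vector(T, disc.rate_costs)
    pt = trace.person_time

    prop = (
        np.asarray(prop_effective_per_cycle, dtype=float)[:T]
        if prop_effective_per_cycle is not None
        else np.full(T, eff.prop_effective(arm))
    )
    drug = (
        np.asarray(drug_cost_per_cycle, dtype=float)[:T]
        if drug_cost_per_cycle is not None
        else np.full(T, costs.arm_drug_cost(arm))
    )

    ly = float(df_out @ pt)
    etpy = float(df_out @ (prop * pt))

    inc = trace.incidence
    events = {ev.value: float(inc[ev].sum()) for ev in EVENT_ORDER}
    events["fatal_cvd"] = events["chd_death"] + events["is_death"]
    events["revascularisation"] = float(trace.revascularisations.sum())
    events["any_cvd"] = sum(events[ev.value] for ev in EVENT_ORDER)

    medication = float(df_cost @ (drug * pt))
    non_fatal = float(
        df_cost
        @ (
            inc[Event.MI] * costs.acute["mi"]
            + inc[Event.IS] * costs.acute["is"]
            + inc[Event.HF] * costs.acute["hf"]
        )
    )
    fatal = float(
        df_cost
        @ (
            inc[Event.CHD_DEATH] * costs.acute["chd_death"]
            + inc[Event.IS_DEATH] * costs.acute["is_death"]
        )
    )
    revasc_cost = float(
        df_cost @ (trace.revascularisations * costs.acute["revascularisation"])
    )

    state_pt = trace.state_person_time()  # (T, n)
    post_vec = np.zeros(trace.space.n)
    for i, s in enumerate(trace.space):
        if s.is_chronic:
            post_vec[i] = costs.post_cost_for_memory(s.memory)
    post_cost = float(df_cost @ (state_pt @ post_vec))

    cost_map = {
        "medication": medication,
        "non_fatal_acute": non_fatal,
        "fatal": fatal,
        "revascularisation": revasc_cost,
        "post_event": post_cost,
    }
    cost_map["total"] = sum(cost_map[c] for c in COST_CATEGORIES)

    return ArmResults(arm=arm, ly=ly, etpy=etpy, events=events, costs=cost_map).validate()


@dataclass
class IncrementalResults:
    """Treatment-minus-control differences and the cost-effectiveness ratio."""

    d_cost: float
    d_etpy: float
    d_ly: float
    icer: Optional[float]
    dominance: str  # "icer", "dominant", "dominated", "equal", "undefined"


def incremental(treated: ArmResults, control: ArmResults) -> IncrementalResults:
    """Incremental results; the ICER is reported only when the intervention
    is both costlier and more effective, otherwise a dominance flag is set."""
    d_cost = treated.total_cost - control.total_cost
    d_etpy = treated.etpy - control.etpy
    d_ly = treated.ly - control.ly
    if d_cost == 0.0 and d_etpy == 0.0:
        return IncrementalResults(d_cost, d_etpy, d_ly, None, "equal")
    if d_etpy > 0.0 and d_cost > 0.0:
        return IncrementalResults(d_cost, d_etpy, d_ly, d_cost / d_etpy, "icer")
    if d_etpy > 0.0 and d_cost <= 0.0:
        return IncrementalResults(d_cost, d_etpy, d_ly, d_cost / d_etpy, "dominant")
    if d_etpy == 0.0 and d_cost > 0.0:
        return IncrementalResults(d_cost, d_etpy, d_ly, None, "undefined")
    if d_etpy < 0.0 and d_cost > 0.0:
        return IncrementalResults(d_cost, d_etpy, d_ly, None, "dominated")
    return IncrementalResults(d_cost, d_etpy, d_ly, None, "undefined")
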