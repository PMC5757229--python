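"""Model configuration: assembly, validation and YAML round-tripping.

Every under-published input is visible and overridable here: the cohort
profile, life table, risk-equation coefficient sets, FH risk adjustment,
rate-ratio table, efficacy inputs, event-type distribution, costs, discount
rates and run controls.  Units follow the field documentation of the
component types (years, mmHg, mg/dL, BGN, proportions in [0, 1]); saved YAML
files carry a unit legend in a comment header.
"""
from __future__ import annotations

import copy
import hashlib
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Union

import yaml

from .econ import CostTable, DiscountSpec
from .effect import EfficacyInputs, RateRatio, RateRatioTable
from .inputs import (
    CohortProfile,
    EventDistributionTable,
    InitialStateDistribution,
    InputError,
    LifeTable,
    default_cohort,
    default_life_table,
    generate_event_distribution,
)
from .risk import RiskAdjustment, RiskCoefficientSet, load_packaged_coefficients

_UNIT_LEGEND = """\
# Model configuration.
# Units: ages/horizons in years; blood pressure in mmHg; lipids in mg/dL
# (1 mmol/L LDL-C = 38.67 mg/dL); costs in BGN (2015); *_frac and shares are
# proportions in [0, 1]; rates are events per person-year; q_all is an annual
# death probability; discount rates are annual.
"""


@dataclass
class ModelConfig:
    """Complete specification of one model run."""

    cohort: CohortProfile = field(default_factory=default_cohort)
    life_table: LifeTable = field(default_factory=default_life_table)
    risk_primary: RiskCoefficientSet = field(
        default_factory=lambda: load_packaged_coefficients("primary_10y")
    )
    risk_secondary: RiskCoefficientSet = field(
        default_factory=lambda: load_packaged_coefficients("secondary_20mo")
    )
    risk_adjustment: RiskAdjustment = field(default_factory=RiskAdjustment)
    rate_ratios: RateRatioTable = field(default_factory=RateRatioTable)
    efficacy: EfficacyInputs = field(default_factory=EfficacyInputs)
    event_distribution: EventDistributionTable = field(
        default_factory=lambda: generate_event_distribution(20150422)
    )
    costs: CostTable = field(default_factory=CostTable)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    revascularisation_rates: Dict[str, float] = field(
        default_factory=lambda: {"ecvd": 0.10, "acute_mi": 0.45, "post_mi": 0.07}
    )
    target_10y_risk: float = 0.55
    region_flag: bool = True
    mortality_convention: str = "cause_deleted"  # or "simple"
    horizon: Union[str, int] = "lifetime"
    cycle_length_years: float = 1.0
    max_age: float = 110.0
    treatment_duration_years: Optional[int] = None  # None = lifelong
    seed: int = 0

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "cohort": asdict(self.cohort),
            "life_table": self.life_table.to_records(),
            "risk_primary": self.risk_primary.to_dict(),
            "risk_secondary": self.risk_secondary.to_dict(),
            "risk_adjustment": asdict(self.risk_adjustment),
            "rate_ratios": {
                name: {
                    "rr": r.rr,
                    "ci": list(r.ci),
                    "ci_level": r.ci_level,
                    "fixed": r.fixed,
                }
                for name, r in self.rate_ratios.ratios.items()
            },
            "efficacy": asdict(self.efficacy),
            "event_distribution": self.event_distribution.to_frame().to_dict(
                orient="records"
            ),
            "costs": asdict(self.costs),
            "discount": asdict(self.discount),
            "revascularisation_rates": dict(self.revascularisation_rates),
            "target_10y_risk": self.target_10y_risk,
            "region_flag": self.region_flag,
            "mortality_convention": self.mortality_convention,
            "horizon": self.horizon,
            "cycle_length_years": self.cycle_length_years,
            "max_age": self.max_age,
            "treatment_duration_years": self.treatment_duration_years,
            "seed": self.seed,
        }
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        import pandas as pd

        cohort_d = dict(d["cohort"])
        cohort_d["initial_state_dist"] = InitialStateDistribution(
            **cohort_d["initial_state_dist"]
        )
        eff_d = dict(d["efficacy"])
        for key in list(eff_d):
            if key.endswith("_ci"):
                eff_d[key] = tuple(eff_d[key])
        adj_d = dict(d["risk_adjustment"])
        for key in list(adj_d):
            if key.endswith("_ci"):
                adj_d[key] = tuple(adj_d[key])
        return cls(
            cohort=CohortProfile(**cohort_d),
            life_table=LifeTable.from_records(d["life_table"]),
            risk_primary=RiskCoefficientSet.from_dict(d["risk_primary"]),
            risk_secondary=RiskCoefficientSet.from_dict(d["risk_secondary"]),
            risk_adjustment=RiskAdjustment(**adj_d),
            rate_ratios=RateRatioTable(
                {
                    name: RateRatio(
                        r["rr"], tuple(r["ci"]), r["ci_level"], r.get("fixed", False)
                    )
                    for name, r in d["rate_ratios"].items()
                }
            ),
            efficacy=EfficacyInputs(**eff_d),
            event_distribution=EventDistributionTable.from_frame(
                pd.DataFrame.from_records(d["event_distribution"])
            ),
            costs=CostTable(**d["costs"]),
            discount=DiscountSpec(**d["discount"]),
            revascularisation_rates=dict(d["revascularisation_rates"]),
            target_10y_risk=d["target_10y_risk"],
            region_flag=d["region_flag"],
            mortality_convention=d["mortality_convention"],
            horizon=d["horizon"],
            cycle_length_years=d["cycle_length_years"],
            max_age=d["max_age"],
            treatment_duration_years=d["treatment_duration_years"],
            seed=d["seed"],
        )

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def content_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelConfig) and self.to_dict() == other.to_dict()


def _plainify(obj):
    """Recursively convert numpy scalars/arrays and tuples to plain Python."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plainify(v) for v in obj.tolist()]
    return obj


def default_config(seed: int = 0) -> ModelConfig:
    """The packaged base-case configuration."""
    return ModelConfig(seed=seed)


def validate_config(cfg: ModelConfig) -> ModelConfig:
    """Validate every component invariant; returns the (normalised) config.

    Raises :class:`~etpymodel.inputs.InputError` naming the first failed
    invariant.
    """
    cfg.cohort.validate()
    cfg.life_table.validate()
    cfg.risk_primary.validate()
    cfg.risk_secondary.validate()
    if cfg.risk_primary.model_id != "primary_10y":
        raise InputError("ModelConfig: risk_primary must be a primary_10y set")
    if cfg.risk_secondary.model_id != "secondary_20mo":
        raise InputError("ModelConfig: risk_secondary must be a secondary_20mo set")
    if "eastern_europe_or_middle_east" not in cfg.risk_secondary.coefficients:
        raise InputError(
            "ModelConfig: secondary risk equation lacks the "
            "'eastern_europe_or_middle_east' region coefficient"
        )
    cfg.risk_adjustment.validate()
    cfg.rate_ratios.validate()
    cfg.efficacy.validate()
    cfg.event_distribution = cfg.event_distribution.normalised().validate()
    cfg.costs.validate()
    cfg.discount.validate()
    for k, v in cfg.revascularisation_rates.items():
        if v < 0:
            raise InputError(f"ModelConfig: negative revascularisation rate for {k}")
    if not 0.0 < cfg.target_10y_risk < 1.0:
        raise InputError("ModelConfig: target_10y_risk must be in (0, 1)")
    if cfg.cycle_length_years != 1.0:
        raise InputError("ModelConfig: the model employs annual cycles (cycle_length_years = 1)")
    if cfg.horizon != "lifetime" and (
        not isinstance(cfg.horizon, int) or cfg.horizon < 1
    ):
        raise InputError("ModelConfig: horizon must be 'lifetime' or a positive integer")
    if cfg.treatment_duration_years is not None and cfg.treatment_duration_years < 0:
        raise InputError("ModelConfig: treatment_duration_years must be non-negative")
    if cfg.mortality_convention not in ("cause_deleted", "simple"):
        raise InputError("ModelConfig: unknown mortality convention")
    return cfg


def save_config(cfg: ModelConfig, path) -> None:
    """Write the configuration as human-editable YAML with a unit legend."""
    with open(path, "w") as fh:
        fh.write(_UNIT_LEGEND)
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        return validate_config(ModelConfig.from_dict(yaml.safe_load(fh)))
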