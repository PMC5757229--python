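"""Baseline cardiovascular risk engine.

Turns multi-horizon risk-equation predictions into the annual event rates the
Markov engine consumes:

* a 10-year primary-prevention risk score evaluated at the cohort means for
  the no-CVD state;
* a 20-month secondary-prevention ("next cardiovascular event") score with a
  regional coefficient for Eastern Europe / Middle East, evaluated per
  post-event state;
* an age-effect removal that freezes predictions at the baseline age by
  absorbing the age term into the intercept;
* conversion of a familial-hypercholesterolaemia odds-ratio pair into a
  pooled rate ratio (default 7.1) applied to all predicted rates; and
* calibration of the primary-prevention rate to a configured 10-year
  >=1-event risk (55% in the base case).

Risk <-> rate conversions assume a constant hazard within each horizon.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

from scipy.special import expit

from .inputs import CohortProfile, InputError
from .states import FLAG_ORDER, Flag

SECONDARY_HORIZON_YEARS = 20.0 / 12.0


# --------------------------------------------------------------------------
# risk <-> rate conversions
# --------------------------------------------------------------------------


def risk_to_annual_rate(p: float, horizon: float) -> float:
    """Annual event rate implied by a cumulative risk over ``horizon`` years,
    under a constant hazard: ``-ln(1 - p) / horizon``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p}")
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return -math.log1p(-p) / horizon


def annual_rate_to_prob(rate: float) -> float:
    """Annual transition probability for a constant annual rate:
    ``1 - exp(-rate)``."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -math.expm1(-rate)


# --------------------------------------------------------------------------
# coefficient sets
# --------------------------------------------------------------------------

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": math.log,
}


@dataclass
class Coefficient:
    value: float
    transform: str = "identity"

    def apply(self, x: float) -> float:
        try:
            f = _TRANSFORMS[self.transform]
        except KeyError:
            raise InputError(f"unknown covariate transform {self.transform!r}")
        return self.value * f(x)


@dataclass
class RiskCoefficientSet:
    """A declarative risk equation: link, horizon, intercept and coefficients.

    Coefficient sets are data, not code -- the packaged sets are synthetic
    stand-ins, and published coefficient values can be loaded from JSON
    without code changes.  ``calibration_scalar`` multiplies the predicted
    annual rate; ``None`` requests automatic calibration to the configured
    10-year risk target (primary prevention only).
    """

    model_id: str  # "primary_10y" or "secondary_20mo"
    horizon_years: float
    link: str  # "logistic" or "baseline_survival"
    intercept: float
    coefficients: Dict[str, Coefficient]
    baseline_survival: Optional[float] = None
    calibration_scalar: Optional[float] = 1.0

    def validate(self) -> "RiskCoefficientSet":
        if self.model_id == "primary_10y":
            if abs(self.horizon_years - 10.0) > 1e-9:
                raise InputError("RiskCoefficientSet: primary_10y horizon must be 10 years")
        elif self.model_id == "secondary_20mo":
            if abs(self.horizon_years - SECONDARY_HORIZON_YEARS) > 1e-9:
                raise InputError(
                    "RiskCoefficientSet: secondary_20mo horizon must be 20 months"
                )
        else:
            raise InputError(f"RiskCoefficientSet: unknown model_id {self.model_id!r}")
        if self.link not in ("logistic", "baseline_survival"):
            raise InputError(f"RiskCoefficientSet: unknown link {self.link!r}")
        if self.link == "baseline_survival" and not (
            self.baseline_survival and 0.0 < self.baseline_survival < 1.0
        ):
            raise InputError(
                "RiskCoefficientSet: baseline_survival link requires S0 in (0, 1)"
            )
        if self.calibration_scalar is not None and self.calibration_scalar <= 0:
            raise InputError("RiskCoefficientSet: calibration_scalar must be positive")
        return self

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        missing = [name for name in self.coefficients if name not in covariates]
        if missing:
            raise InputError(
                f"missing covariates for {self.model_id}: {', '.join(sorted(missing))}"
            )
        return self.intercept + sum(
            coef.apply(covariates[name]) for name, coef in self.coefficients.items()
        )

    def predict(self, covariates: Mapping[str, float]) -> float:
        """Cumulative event probability over the equation's horizon."""
        lp = self.linear_predictor(covariates)
        if self.link == "logistic":
            return float(expit(lp))
        return 1.0 - self.baseline_survival ** math.exp(lp)

    # -- IO ---------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "horizon_years": self.horizon_years,
            "link": self.link,
            "intercept": self.intercept,
            "baseline_survival": self.baseline_survival,
            "calibration_scalar": self.calibration_scalar,
            "coefficients": {
                name: {"value": c.value, "transform": c.transform}
                for name, c in self.coefficients.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskCoefficientSet":
        return cls(
            model_id=d["model_id"],
            horizon_years=float(d["horizon_years"]),
            link=d["link"],
            intercept=float(d["intercept"]),
            coefficients={
                name: Coefficient(float(spec["value"]), spec.get("transform", "identity"))
                for name, spec in d["coefficients"].items()
            },
            baseline_survival=d.get("baseline_survival"),
            calibration_scalar=d.get("calibration_scalar"),
        ).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskCoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_packaged_coefficients(model_id: str) -> RiskCoefficientSet:
    """Load one of the packaged synthetic coefficient sets."""
    fname = {
        "primary_10y": "synthetic_primary_10y.json",
        "secondary_20mo": "synthetic_secondary_20mo.json",
    }[model_id]
    text = resources.files("etpymodel.data").joinpath(fname).read_text()
    return RiskCoefficientSet.from_dict(json.loads(text))


# --------------------------------------------------------------------------
# covariate construction
# --------------------------------------------------------------------------


def profile_covariates(profile: CohortProfile) -> Dict[str, float]:
    """Cohort-mean covariate values shared by both risk equations."""
    return {
        "age": profile.age_mean,
        "female": profile.female_frac,
        "smoking": profile.smoking_frac,
        "t2dm": profile.t2dm_frac,
        "htn_therapy": profile.htn_therapy_frac,
        "asa": profile.asa_frac,
        "sbp": profile.sbp_mean,
        "tc": profile.tc_mean,
        "hdl": profile.hdl_mean,
        "low_bmi": profile.low_bmi_frac,
        "vascular_beds": profile.vascular_beds,
        "afib": profile.afib_frac,
    }


def secondary_covariates(
    profile: CohortProfile, memory, region_flag: bool
) -> Dict[str, float]:
    """Covariates for the secondary-prevention equation in a given prior-event
    state; the region indicator is set iff ``region_flag``."""
    cov = profile_covariates(profile)
    mem = frozenset(memory)
    cov["ecvd"] = 1.0 if Flag.ECVD in mem else 0.0
    cov["prior_mi"] = 1.0 if Flag.POST_MI in mem else 0.0
    cov["prior_is"] = 1.0 if Flag.POST_IS in mem else 0.0
    cov["prior_hf"] = 1.0 if Flag.POST_HF in mem else 0.0
    cov["eastern_europe_or_middle_east"] = 1.0 if region_flag else 0.0
    return cov


def primary_prevention_risk(
    profile: CohortProfile, coeffs: RiskCoefficientSet
) -> float:
    """Cohort 10-year risk of a first CVD event (uncalibrated prediction)."""
    if coeffs.model_id != "primary_10y":
        raise InputError("primary_prevention_risk requires a primary_10y coefficient set")
    return coeffs.predict(profile_covariates(profile))


def secondary_prevention_risk(
    profile: CohortProfile,
    coeffs: RiskCoefficientSet,
    region_flag: bool,
    memory=frozenset({Flag.ECVD}),
) -> float:
    """20-month risk of the next CVD event for a prior-event state."""
    if coeffs.model_id != "secondary_20mo":
        raise InputError(
            "secondary_prevention_risk requires a secondary_20mo coefficient set"
        )
    return coeffs.predict(secondary_covariates(profile, memory, region_flag))


def remove_age_effect(
    coeffs: RiskCoefficientSet, baseline_age: float
) -> RiskCoefficientSet:
    """Freeze the equation's age dependence at ``baseline_age``.

    The age term evaluated at the baseline age is absorbed into the intercept
    and the age coefficient is set to zero, so predictions no longer rise as
    the cohort ages through the trace.  Idempotent; predictions at the
    baseline age are unchanged.
    """
    if "age" not in coeffs.coefficients:
        return coeffs
    age_coef = coeffs.coefficients["age"]
    new_coeffs = dict(coeffs.coefficients)
    new_coeffs["age"] = Coefficient(0.0, age_coef.transform)
    return replace(
        coeffs,
        intercept=coeffs.intercept + age_coef.apply(baseline_age),
        coefficients=new_coeffs,
    )


# --------------------------------------------------------------------------
# FH risk adjustment
# --------------------------------------------------------------------------


@dataclass
class RiskAdjustment:
    """Excess CVD risk of FH patients relative to other hyperlipidaemics.

    Case-control odds ratios (off/on lipid-lowering therapy) are converted to
    risk ratios against a reference event risk and pooled over the treated
    share; the published pooled rate ratio of 7.1 (95% CI 5.7-8.7) is the
    packaged default and, when set, overrides the computation.
    """

    or_fh_off: float = 13.2
    or_fh_off_ci: Tuple[float, float] = (10.0, 17.4)
    or_fh_on: float = 10.3
    or_fh_on_ci: Tuple[float, float] = (7.8, 13.8)
    treated_share: float = 0.5
    reference_risk: float = 0.2
    pooled_rr: Optional[float] = 7.1
    pooled_rr_ci: Tuple[float, float] = (5.7, 8.7)

    def validate(self) -> "RiskAdjustment":
        if self.pooled_rr is not None and self.pooled_rr <= 0:
            raise InputError("RiskAdjustment: pooled_rr must be positive")
        if not 0.0 < self.reference_risk < 1.0:
            raise InputError("RiskAdjustment: reference_risk must be in (0, 1)")
        if not 0.0 <= self.treated_share <= 1.0:
            raise InputError("RiskAdjustment: treated_share must be in [0, 1]")
        return self


def _or_to_rr(odds_ratio: float, p0: float) -> float:
    # Zhang-Yu conversion of an odds ratio to a risk ratio at baseline risk p0.
    return odds_ratio / (1.0 - p0 + p0 * odds_ratio)


def pool_fh_rate_ratio(adj: RiskAdjustment) -> float:
    """Pooled FH-vs-non-FH event rate ratio.

    Default mode returns the supplied ``pooled_rr`` (7.1).  In computation
    mode (``pooled_rr=None``) each odds ratio is converted via
    ``RR = OR / (1 - p0 + p0 * OR)`` and the on/off-therapy ratios are pooled
    by the treated share.
    """
    adj.validate()
    if adj.pooled_rr is not None:
        return adj.pooled_rr
    rr_off = _or_to_rr(adj.or_fh_off, adj.reference_risk)
    rr_on = _or_to_rr(adj.or_fh_on, adj.reference_risk)
    return adj.treated_share * rr_on + (1.0 - adj.treated_share) * rr_off


# --------------------------------------------------------------------------
# annual event rates
# --------------------------------------------------------------------------


@dataclass
class AnnualEventRates:
    """Annual any-CVD-event rates per health state plus procedure rates.

    ``state_rates`` keys the five rate-bearing contexts (``no_cvd``, ``ecvd``,
    ``post_mi``, ``post_is``, ``post_hf``); composite and acute states derive
    their rate from these via the maximum-risk rule.
    ``revascularisation`` gives annual procedure rates for the ECVD, acute-MI
    and post-MI states.
    """

    state_rates: Dict[str, float]
    revascularisation: Dict[str, float] = field(
        default_factory=lambda: {"ecvd": 0.0, "acute_mi": 0.0, "post_mi": 0.0}
    )

    def validate(self) -> "AnnualEventRates":
        for k, v in {**self.state_rates, **self.revascularisation}.items():
            if v < 0:
                raise InputError(f"AnnualEventRates: negative rate for {k}")
        return self

    def any_event_rate(self, state) -> float:
        """Any-event rate of a state: its own rate, or the maximum over the
        chronic states it remembers (composite/acute maximum-risk rule)."""
        from .states import Kind

        if state.kind is Kind.NO_CVD:
            return self.state_rates["no_cvd"]
        if state.is_death:
            raise InputError("death states carry no event rate")
        return max(self.state_rates[f.value] for f in state.memory)

    def scaled(self, factor: float) -> "AnnualEventRates":
        return AnnualEventRates(
            {k: v * factor for k, v in self.state_rates.items()},
            dict(self.revascularisation),
        )

    @classmethod
    def zeros(cls) -> "AnnualEventRates":
        return cls({k: 0.0 for k in ("no_cvd", "ecvd", "post_mi", "post_is", "post_hf")})


def calibrate_primary_scalar(
    profile: CohortProfile,
    coeffs: RiskCoefficientSet,
    pooled_rr: float,
    target_10y_risk: float,
) -> float:
    """Multiplicative calibration scalar on the primary-prevention rate.

    Chosen jointly with the FH adjustment so the no-CVD state's final annual
    rate equals ``-ln(1 - target) / 10``, i.e. the configured 10-year
    >=1-event risk is reproduced exactly under the constant-hazard mapping.
    """
    raw_p = primary_prevention_risk(profile, coeffs)
    raw_rate = risk_to_annual_rate(raw_p, coeffs.horizon_years)
    target_rate = risk_to_annual_rate(target_10y_risk, 10.0)
    if raw_rate <= 0:
        raise InputError("cannot calibrate: predicted primary-prevention risk is zero")
    return target_rate / (raw_rate * pooled_rr)


def baseline_rates(cfg) -> AnnualEventRates:
    """Annual baseline (untreated) event rates for every rate-bearing state.

    The no-CVD rate is the calibrated primary-prevention prediction times the
    pooled FH rate ratio; each secondary state's rate is the 20-month
    prediction with that state's prior-event indicators, annualised and
    multiplied by the same pooled ratio.  Revascularisation procedure rates
    come from the config.
    """
    profile = cfg.cohort
    rr = pool_fh_rate_ratio(cfg.risk_adjustment)

    primary = remove_age_effect(cfg.risk_primary, profile.age_mean)
    secondary = remove_age_effect(cfg.risk_secondary, profile.age_mean)

    scalar = primary.calibration_scalar
    if scalar is None:
        scalar = calibrate_primary_scalar(profile, primary, rr, cfg.target_10y_risk)
    raw_primary = risk_to_annual_rate(
        primary_prevention_risk(profile, primary), primary.horizon_years
    )
    rates = {"no_cvd": raw_primary * scalar * rr}

    sec_scalar = secondary.calibration_scalar or 1.0
    for flag in FLAG_ORDER:
        p = secondary_prevention_risk(
            profile, secondary, cfg.region_flag, memory=frozenset({flag})
        )
        rates[flag.value] = (
            risk_to_annual_rate(p, secondary.horizon_years) * sec_scalar * rr
        )

    return AnnualEventRates(rates, dict(cfg.revascularisation_rates)).validate()
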