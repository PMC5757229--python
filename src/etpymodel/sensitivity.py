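"""Deterministic (one-way) and probabilistic sensitivity analysis.

Distribution families follow standard health-economic practice: beta for the
relative LDL-C reduction and the proportions effectively treated, gamma for
health-state costs (standard error 10% of the mean), lognormal for the
rate ratios and the baseline CVD risk adjustment.  Parameters are sampled
independently; out-of-support draws are resampled (not truncated) with an
audit count.  The PSA summarises by the ratio of means (mean incremental
cost over mean incremental ETPY); the per-iteration draws are also exported.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, validate_config
from .inputs import InputError
from .pipeline import run_base_case

Setter = Callable[[ModelConfig, float], None]


# --------------------------------------------------------------------------
# parameter registry: where each named parameter lives in the config
# --------------------------------------------------------------------------


def _set_rr(event: str) -> Setter:
    def setter(cfg: ModelConfig, v: float) -> None:
        cfg.rate_ratios.ratios[event] = replace(cfg.rate_ratios.ratios[event], rr=v)

    return setter


def _set_acute_cost(key: str) -> Setter:
    def setter(cfg: ModelConfig, v: float) -> None:
        cfg.costs.acute[key] = v

    return setter


def _set_post_cost(key: str) -> Setter:
    def setter(cfg: ModelConfig, v: float) -> None:
        cfg.costs.post[key] = v

    return setter


def _set_efficacy(attr: str, ci_attr: str) -> Setter:
    # widen the stored CI when a draw/bound falls outside it, so the sampled
    # config still satisfies the input invariant "lo <= value <= hi"
    def setter(cfg: ModelConfig, v: float) -> None:
        setattr(cfg.efficacy, attr, v)
        lo, hi = getattr(cfg.efficacy, ci_attr)
        setattr(cfg.efficacy, ci_attr, (min(lo, v), max(hi, v)))

    return setter


PARAMETER_SETTERS: Dict[str, Setter] = {
    "ldl_reduction_pct": _set_efficacy("ldl_reduction_pct", "ldl_reduction_ci"),
    "prop_effective_treatment": _set_efficacy(
        "prop_effective_treatment", "prop_effective_treatment_ci"
    ),
    "prop_effective_control": _set_efficacy(
        "prop_effective_control", "prop_effective_control_ci"
    ),
    "pooled_rr": lambda cfg, v: setattr(cfg.risk_adjustment, "pooled_rr", v),
    "rr_mi": _set_rr("mi"),
    "rr_is": _set_rr("is"),
    "rr_chd_death": _set_rr("chd_death"),
    "rr_revascularisation": _set_rr("revascularisation"),
    "discount_costs": lambda cfg, v: setattr(cfg.discount, "rate_costs", v),
    "discount_outcomes": lambda cfg, v: setattr(cfg.discount, "rate_outcomes", v),
    "treatment_duration_years": lambda cfg, v: setattr(
        cfg, "treatment_duration_years", int(v)
    ),
}
for _key in ("mi", "is", "hf", "chd_death", "is_death", "revascularisation"):
    PARAMETER_SETTERS[f"cost_acute_{_key}"] = _set_acute_cost(_key)
for _key in ("ecvd", "post_mi", "post_is", "post_hf"):
    PARAMETER_SETTERS[f"cost_post_{_key}"] = _set_post_cost(_key)


def apply_parameter(cfg: ModelConfig, name: str, value: float) -> None:
    try:
        PARAMETER_SETTERS[name](cfg, value)
    except KeyError:
        raise InputError(f"unknown sensitivity parameter {name!r}")


# --------------------------------------------------------------------------
# parameter specifications and distribution fitting
# --------------------------------------------------------------------------


@dataclass
class ParameterSpec:
    """A parameter with its uncertainty distribution.

    Provide ``se`` directly or a confidence interval (``ci`` at ``ci_level``);
    :func:`ci_to_distribution` fills the family's distribution parameters
    (``dist_params``).
    """

    name: str
    family: str  # "beta", "gamma", "lognormal", "fixed"
    mean: float
    se: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    ci_level: float = 0.95
    dist_params: Dict[str, float] = field(default_factory=dict)


def _z(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


def ci_to_distribution(spec: ParameterSpec) -> ParameterSpec:
    """Fill the distribution parameters from the mean and SE (or CI).

    beta: method of moments from mean and SE; gamma: shape ``(mean/SE)^2``,
    scale ``SE^2/mean``; lognormal: ``sigma`` from the ratio of CI bounds on
    the log scale, with the location chosen so the distribution's mean equals
    the point estimate.
    """
    if spec.family == "fixed":
        return spec
    se = spec.se
    if spec.family == "lognormal":
        if spec.ci is None:
            if se is None:
                raise InputError(f"{spec.name}: lognormal needs a CI or SE")
            sigma = se / spec.mean  # first-order log-scale SD
        else:
            lo, hi = spec.ci
            if lo <= 0 or hi <= lo:
                raise InputError(f"{spec.name}: invalid lognormal CI {spec.ci}")
            sigma = (np.log(hi) - np.log(lo)) / (2.0 * _z(spec.ci_level))
        if spec.mean <= 0:
            raise InputError(f"{spec.name}: lognormal mean must be positive")
        mu = float(np.log(spec.mean) - 0.5 * sigma**2)  # mean-matching location
        spec.dist_params = {"mu": mu, "sigma": float(sigma)}
        return spec
    if se is None:
        if spec.ci is None:
            raise InputError(f"{spec.name}: need an SE or CI")
        lo, hi = spec.ci
        se = (hi - lo) / (2.0 * _z(spec.ci_level))
    if spec.family == "beta":
        m = spec.mean
        if not 0.0 < m < 1.0:
            raise InputError(f"{spec.name}: beta mean must be in (0, 1)")
        nu = m * (1.0 - m) / se**2 - 1.0
        if nu <= 0:
            raise InputError(f"{spec.name}: SE too large for a beta distribution")
        spec.dist_params = {"alpha": m * nu, "beta": (1.0 - m) * nu}
        return spec
    if spec.family == "gamma":
        if spec.mean <= 0:
            raise InputError(f"{spec.name}: gamma mean must be positive")
        spec.dist_params = {"shape": (spec.mean / se) ** 2, "scale": se**2 / spec.mean}
        return spec
    raise InputError(f"{spec.name}: unknown family {spec.family!r}")


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.mean
    if not spec.dist_params:
        ci_to_distribution(spec)
    p = spec.dist_params
    if spec.family == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if spec.family == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if spec.family == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    raise InputError(f"{spec.name}: unknown family {spec.family!r}")


def distribution_ci(spec: ParameterSpec, level: float = 0.95) -> Tuple[float, float]:
    """Equal-tailed interval of the fitted distribution (used for DSA bounds)."""
    if not spec.dist_params:
        ci_to_distribution(spec)
    p = spec.dist_params
    z = _z(level)
    if spec.family == "fixed":
        return (spec.mean, spec.mean)
    if spec.family == "beta":
        d = stats.beta(p["alpha"], p["beta"])
    elif spec.family == "gamma":
        d = stats.gamma(p["shape"], scale=p["scale"])
    elif spec.family == "lognormal":
        return (
            float(np.exp(p["mu"] - z * p["sigma"])),
            float(np.exp(p["mu"] + z * p["sigma"])),
        )
    else:
        raise InputError(f"{spec.name}: unknown family {spec.family!r}")
    lo, hi = d.ppf(0.5 - level / 2.0), d.ppf(0.5 + level / 2.0)
    return float(lo), float(hi)


def default_psa_specs(cfg: ModelConfig) -> List[ParameterSpec]:
    """The sampled parameter set of the probabilistic analysis.

    Efficacy proportions and the LDL-C reduction are beta; the pooled FH rate
    ratio and the per-event rate ratios are lognormal (the IS-death ratio is
    fixed at 1 and not sampled); every health-state cost is gamma with an SE
    of 10% of its mean.
    """
    eff = cfg.efficacy
    specs = [
        ParameterSpec("ldl_reduction_pct", "beta", eff.ldl_reduction_pct, ci=eff.ldl_reduction_ci),
        ParameterSpec(
            "prop_effective_treatment",
            "beta",
            eff.prop_effective_treatment,
            ci=eff.prop_effective_treatment_ci,
        ),
        ParameterSpec(
            "prop_effective_control",
            "beta",
            eff.prop_effective_control,
            ci=eff.prop_effective_control_ci,
        ),
        ParameterSpec(
            "pooled_rr",
            "lognormal",
            cfg.risk_adjustment.pooled_rr,
            ci=cfg.risk_adjustment.pooled_rr_ci,
            ci_level=0.95,
        ),
    ]
    for event in ("mi", "is", "chd_death", "revascularisation"):
        r = cfg.rate_ratios.ratios[event]
        specs.append(
            ParameterSpec(f"rr_{event}", "lognormal", r.rr, ci=r.ci, ci_level=r.ci_level)
        )
    for key, value in cfg.costs.acute.items():
        if value > 0:
            specs.append(
                ParameterSpec(f"cost_acute_{key}", "gamma", value, se=0.10 * value)
            )
    for key, value in cfg.costs.post.items():
        if value > 0:
            specs.append(
                ParameterSpec(f"cost_post_{key}", "gamma", value, se=0.10 * value)
            )
    return [ci_to_distribution(s) for s in specs]


# --------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class DsaScenario:
    """A named set of parameter overrides applied to the base config."""

    name: str
    overrides: Dict[str, float] = field(default_factory=dict)


def default_dsa_scenarios(cfg: ModelConfig) -> List[DsaScenario]:
    """Low/high 95% bounds for every uncertain parameter, plus the structural
    scenarios: both discount rates to 0% and treatment duration to 5 years."""
    scenarios: List[DsaScenario] = []
    for spec in default_psa_specs(cfg):
        lo, hi = distribution_ci(spec, 0.95)
        scenarios.append(DsaScenario(f"{spec.name}_low", {spec.name: lo}))
        scenarios.append(DsaScenario(f"{spec.name}_high", {spec.name: hi}))
    scenarios.append(DsaScenario("discount_costs_0pct", {"discount_costs": 0.0}))
    scenarios.append(DsaScenario("discount_outcomes_0pct", {"discount_outcomes": 0.0}))
    scenarios.append(
        DsaScenario("treatment_duration_5y", {"treatment_duration_years": 5})
    )
    return scenarios


def run_dsa(
    cfg: ModelConfig, scenarios: Optional[Sequence[DsaScenario]] = None
) -> pd.DataFrame:
    """Re-run the full pipeline per scenario.

    Returns one row per scenario with the scenario ICER and increments,
    sorted by absolute deviation from the base-case ICER; scenarios with an
    undefined ICER are flagged, not dropped.
    """
    cfg = validate_config(cfg.copy())
    base = run_base_case(cfg)
    base_icer = base.incremental.icer
    if scenarios is None:
        scenarios = default_dsa_scenarios(cfg)
    rows = []
    for sc in scenarios:
        sc_cfg = cfg.copy()
        for name, value in sc.overrides.items():
            apply_parameter(sc_cfg, name, value)
        res = run_base_case(sc_cfg)
        icer = res.incremental.icer
        rows.append(
            {
                "scenario": sc.name,
                "icer": icer,
                "d_cost": res.incremental.d_cost,
                "d_etpy": res.incremental.d_etpy,
                "dominance": res.incremental.dominance,
                "icer_deviation": (icer - base_icer) if icer is not None else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    frame["abs_deviation"] = frame["icer_deviation"].abs()
    frame = frame.sort_values("abs_deviation", ascending=False, kind="mergesort")
    frame.attrs["base_icer"] = base_icer
    return frame.reset_index(drop=True)


def tornado_table(dsa: pd.DataFrame) -> pd.DataFrame:
    """Pair _low/_high scenario rows into one tornado row per parameter."""
    rows = {}
    for _, rec in dsa.iterrows():
        name = rec["scenario"]
        for suffix, col in (("_low", "icer_low"), ("_high", "icer_high")):
            if name.endswith(suffix):
                rows.setdefault(name[: -len(suffix)], {})[col] = rec["icer"]
    out = pd.DataFrame(
        [{"parameter": k, **v} for k, v in rows.items() if len(v) == 2]
    )
    if out.empty:
        return out
    base = dsa.attrs.get("base_icer")
    out["spread"] = (out["icer_high"] - out["icer_low"]).abs()
    if base is not None:
        out["base_icer"] = base
    return out.sort_values("spread", ascending=False).reset_index(drop=True)


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class PsaResult:
    """Monte Carlo draws and ratio-of-means summary of the PSA."""

    draws: pd.DataFrame  # columns: iteration, d_cost, d_etpy, icer
    mean_d_cost: float
    mean_d_etpy: float
    icer: float  # ratio of means
    seed: int
    n_iterations: int
    n_resampled: int = 0

    def ceac(self, thresholds: Sequence[float]) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve: probability that the net
        monetary benefit is non-negative at each willingness-to-pay value."""
        rows = []
        for lam in thresholds:
            nmb = lam * self.draws["d_etpy"] - self.draws["d_cost"]
            rows.append({"threshold": lam, "prob_cost_effective": float((nmb >= 0).mean())})
        return pd.DataFrame(rows)


def _sample_in_support(
    spec: ParameterSpec, rng: np.random.Generator, max_tries: int = 100
) -> Tuple[float, int]:
    resampled = 0
    for _ in range(max_tries):
        v = sample_parameter(spec, rng)
        if spec.family == "beta" and not 0.0 < v < 1.0:
            resampled += 1
            continue
        if spec.family in ("gamma", "lognormal") and v <= 0.0:
            resampled += 1
            continue
        return v, resampled
    raise InputError(f"{spec.name}: could not draw an in-support value")


def run_psa(
    cfg: ModelConfig,
    specs: Optional[Sequence[ParameterSpec]] = None,
    n: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte Carlo PSA: ``n`` independent draws, full pipeline per draw."""
    cfg = validate_config(cfg.copy())
    if specs is None:
        specs = default_psa_specs(cfg)
    rng = np.random.default_rng(seed)
    rows = []
    n_resampled = 0
    for it in range(n):
        draw_cfg = cfg.copy()
        for spec in specs:
            v, extra = _sample_in_support(spec, rng)
            n_resampled += extra
            apply_parameter(draw_cfg, spec.name, v)
        res = run_base_case(draw_cfg)
        rows.append(
            {
                "iteration": it,
                "d_cost": res.incremental.d_cost,
                "d_etpy": res.incremental.d_etpy,
                "icer": res.incremental.icer,
            }
        )
    draws = pd.DataFrame(rows)
    mean_d_cost = float(draws["d_cost"].mean())
    mean_d_etpy = float(draws["d_etpy"].mean())
    return PsaResult(
        draws=draws,
        mean_d_cost=mean_d_cost,
        mean_d_etpy=mean_d_etpy,
        icer=mean_d_cost / mean_d_etpy,
        seed=seed,
        n_iterations=n,
        n_resampled=n_resampled,
    )
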