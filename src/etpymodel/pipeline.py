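"""End-to-end orchestration: config -> rates -> matrices -> trace -> results.

The treated and control arms share baseline rates, life table and event
distribution; they differ in the per-event treatment multipliers
(``RR ** delta_LDL``), the annual drug cost and the proportion of patients
effectively treated.  The cohort ages one year per cycle for the life-table
lookup while CVD risk stays frozen at the baseline age (age-effect removal).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ModelConfig, validate_config
from .econ import ArmResults, IncrementalResults, accumulate_outcomes, incremental
from .effect import delta_ldl_mmol, event_multipliers
from .inputs import InputError
from .markov import CohortTrace, TransitionModel, apply_mortality, build_cycle_core, run_trace
from .risk import AnnualEventRates, baseline_rates
from .states import EVENT_ORDER, Flag, Kind, StateSpace, chronic_state, enumerate_states

ARMS = ("treatment", "control")


def initial_state_vector(cfg: ModelConfig, space: StateSpace) -> np.ndarray:
    """Entry occupancy over the full state space.

    The secondary-prevention composite share is spread over memory pairs by
    the entry distribution's pair weights.
    """
    dist = cfg.cohort.initial_state_dist
    vec = np.zeros(space.n)
    no_cvd_idx = next(i for i, s in enumerate(space) if s.kind is Kind.NO_CVD)
    vec[no_cvd_idx] = dist.no_cvd
    sp_mass = 1.0 - dist.no_cvd
    for name, flag in (
        ("ecvd", Flag.ECVD),
        ("post_mi", Flag.POST_MI),
        ("post_is", Flag.POST_IS),
        ("post_hf", Flag.POST_HF),
    ):
        vec[space.idx(chronic_state({flag}))] += sp_mass * dist.sp_split[name]
    comp_mass = sp_mass * dist.sp_split["composite"]
    for mem, w in dist.composite_pair_weights().items():
        vec[space.idx(chronic_state(mem))] += comp_mass * w
    return vec / vec.sum()


def n_cycles(cfg: ModelConfig) -> int:
    if cfg.horizon == "lifetime":
        return max(1, int(math.ceil(cfg.max_age - cfg.cohort.age_mean)))
    return int(cfg.horizon)


def noncvd_death_probs(cfg: ModelConfig, cycles: int) -> np.ndarray:
    """Per-cycle non-CVD death probability as the cohort ages."""
    age0 = cfg.cohort.age_mean
    return np.array(
        [
            cfg.life_table.noncvd_q(
                age0 + t, cfg.cohort.female_frac, cfg.mortality_convention
            )
            for t in range(cycles)
        ]
    )


@dataclass
class ArmPlan:
    """Per-cycle dynamics and accumulation inputs for one arm."""

    arm: str
    models: List[TransitionModel]
    drug_cost_per_cycle: np.ndarray
    prop_effective_per_cycle: np.ndarray


def build_arm_plan(
    cfg: ModelConfig,
    arm: str,
    space: Optional[StateSpace] = None,
    rates: Optional[AnnualEventRates] = None,
) -> ArmPlan:
    """Assemble per-cycle transition models and cost/effectiveness schedules.

    A finite ``treatment_duration_years`` switches the treated arm to
    control-arm dynamics, drug cost and attainment after the treatment ends.
    """
    if arm not in ARMS:
        raise InputError(f"unknown arm {arm!r}")
    space = space or enumerate_states()
    rates = rates or baseline_rates(cfg)
    cycles = n_cycles(cfg)
    qs = noncvd_death_probs(cfg, cycles)
    delta = delta_ldl_mmol(cfg.efficacy)

    on_core = build_cycle_core(
        space,
        rates,
        cfg.event_distribution,
        event_multipliers(cfg.rate_ratios, delta, on_treatment=(arm == "treatment")),
    )
    duration = cfg.treatment_duration_years
    off_core = None
    if arm == "treatment" and duration is not None and duration < cycles:
        off_core = build_cycle_core(
            space,
            rates,
            cfg.event_distribution,
            event_multipliers(cfg.rate_ratios, delta, on_treatment=False),
        )

    models, drug, prop = [], [], []
    on_drug = cfg.costs.arm_drug_cost(arm)
    off_drug = cfg.costs.arm_drug_cost("control")
    on_prop = cfg.efficacy.prop_effective(arm)
    off_prop = cfg.efficacy.prop_effective("control")
    for t in range(cycles):
        on = duration is None or arm == "control" or t < duration
        core = on_core if on else off_core
        models.append(apply_mortality(core, float(qs[t])))
        drug.append(on_drug if on else off_drug)
        prop.append(on_prop if on else off_prop)

    return ArmPlan(arm, models, np.asarray(drug), np.asarray(prop))


def run_arm(
    cfg: ModelConfig,
    arm: str,
    space: Optional[StateSpace] = None,
    rates: Optional[AnnualEventRates] = None,
) -> Tuple[CohortTrace, ArmResults]:
    plan = build_arm_plan(cfg, arm, space, rates)
    space = plan.models[0].space
    trace = run_trace(plan.models, initial_state_vector(cfg, space))
    results = accumulate_outcomes(
        trace,
        cfg.efficacy,
        cfg.costs,
        cfg.discount,
        arm,
        drug_cost_per_cycle=plan.drug_cost_per_cycle,
        prop_effective_per_cycle=plan.prop_effective_per_cycle,
    )
    return trace, results


@dataclass
class BaseCaseResults:
    """Both arms plus incremental results of one deterministic run."""

    treatment: ArmResults
    control: ArmResults
    incremental: IncrementalResults
    trace_treatment: CohortTrace
    trace_control: CohortTrace

    def event_rate_reduction(self) -> Dict[str, float]:
        """Relative reductions in lifetime event rates (per undiscounted
        person-year), overall and decomposed, plus the per-mmol/L equivalent."""
        delta = None
        pt_t = self.trace_treatment.person_time.sum()
        pt_c = self.trace_control.person_time.sum()
        out: Dict[str, float] = {}
        rate_t = self.treatment.events["any_cvd"] / pt_t
        rate_c = self.control.events["any_cvd"] / pt_c
        out["any_cvd"] = 1.0 - rate_t / rate_c
        nf_t = sum(self.treatment.events[e] for e in ("mi", "is", "hf")) / pt_t
        nf_c = sum(self.control.events[e] for e in ("mi", "is", "hf")) / pt_c
        out["non_fatal_acute"] = 1.0 - nf_t / nf_c
        fat_t = self.treatment.events["fatal_cvd"] / pt_t
        fat_c = self.control.events["fatal_cvd"] / pt_c
        out["cvd_death"] = 1.0 - fat_t / fat_c
        return out


def run_base_case(cfg: ModelConfig) -> BaseCaseResults:
    """Validate the config and run both arms to incremental results."""
    cfg = validate_config(cfg)
    space = enumerate_states()
    rates = baseline_rates(cfg)
    trace_t, res_t = run_arm(cfg, "treatment", space, rates)
    trace_c, res_c = run_arm(cfg, "control", space, rates)
    return BaseCaseResults(res_t, res_c, incremental(res_t, res_c), trace_t, trace_c)


def per_mmol_reduction(overall_reduction: float, delta_mmol: float) -> float:
    """Per-1-mmol/L event-rate reduction implied by an overall reduction
    achieved at ``delta_mmol`` of LDL-C lowering."""
    if not 0.0 <= overall_reduction < 1.0:
        raise ValueError("overall reduction must be in [0, 1)")
    return 1.0 - (1.0 - overall_reduction) ** (1.0 / delta_mmol)


def ten_year_first_event_risk(cfg: ModelConfig, cycles: int = 10) -> float:
    """Net 10-year >=1-CVD-event risk of the primary-prevention state,
    recomputed from an untreated trace.

    Starts the whole cohort in the no-CVD state, steps the control-arm
    dynamics and compounds the per-cycle first-event probability among
    survivors of non-CVD death.  With the base config this recovers the
    calibration target.
    """
    cfg = validate_config(cfg.copy())
    cfg.horizon = cycles
    space = enumerate_states()
    plan = build_arm_plan(cfg, "control", space)
    no_cvd_idx = next(i for i, s in enumerate(space) if s.kind is Kind.NO_CVD)
    initial = np.zeros(space.n)
    initial[no_cvd_idx] = 1.0
    trace = run_trace(plan.models, initial, stop_alive=0.0)
    qs = noncvd_death_probs(cfg, cycles)
    surv_no_event = 1.0
    for t in range(min(cycles, trace.n_cycles)):
        occ = trace.occupancy[t, no_cvd_idx]
        if occ <= 0:
            break
        events = sum(
            trace.occupancy[t, no_cvd_idx] * plan.models[t].event_probs[no_cvd_idx, k]
            for k in range(len(EVENT_ORDER))
        )
        p_event = events / (occ * (1.0 - qs[t]))
        surv_no_event *= 1.0 - p_event
    return 1.0 - surv_no_event
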