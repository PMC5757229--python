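"""The Markov engine: per-cycle transition matrices and the cohort trace.

Within a cycle the event sequence is: non-CVD death first, then at most one
CVD event among survivors.  The any-event probability of a state derives from
its annual rate (composite maximum-risk rule applied) and is split across
MI / IS / HF / CV death by the prior-event context's event-distribution row;
CV deaths split into IS death and CHD death by the cerebrovascular fraction.
Acute states last exactly one cycle and deposit into the chronic state for
their memory set.  Person-time and costs use the trapezoidal half-cycle
correction; incidence is recorded at the transition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .inputs import EventDistributionTable, InputError, LifeTable
from .risk import AnnualEventRates, annual_rate_to_prob
from .states import (
    EVENT_ORDER,
    Event,
    Flag,
    HealthState,
    Kind,
    NON_CVD_DEATH,
    CHD_DEATH,
    IS_DEATH,
    StateSpace,
    acute_state,
    chronic_state,
)

_ROW_TOL = 1e-10

_UNIT_MULTIPLIERS = {
    "mi": 1.0,
    "is": 1.0,
    "hf": 1.0,
    "chd_death": 1.0,
    "is_death": 1.0,
    "revasc_chronic": 1.0,
    "revasc_acute_mi": 1.0,
}


@dataclass
class CycleCore:
    """Age-independent part of one cycle's dynamics.

    ``conditional`` is the transition matrix conditional on surviving non-CVD
    death (death rows are absorbing unit vectors); ``event_cond`` holds the
    per-state probabilities of each CVD event conditional on surviving
    non-CVD death; ``revasc_rates`` are annual procedure rates applied to
    state occupancy.
    """

    space: StateSpace
    conditional: np.ndarray
    event_cond: np.ndarray  # (n_states, n_events)
    revasc_rates: np.ndarray  # (n_states,)


@dataclass
class TransitionModel:
    """One cycle's full dynamics: a row-stochastic matrix plus event flows."""

    space: StateSpace
    matrix: np.ndarray
    event_probs: np.ndarray  # (n_states, n_events): unconditional per-cycle
    revasc_rates: np.ndarray

    def validate(self) -> "TransitionModel":
        n = self.space.n
        if self.matrix.shape != (n, n):
            raise InputError("TransitionModel: matrix shape mismatch")
        if (self.matrix < -_ROW_TOL).any():
            raise InputError("TransitionModel: negative transition probability")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            bad = self.space[int(np.abs(sums - 1.0).argmax())]
            raise InputError(f"TransitionModel: row for {bad.label} does not sum to 1")
        for i in self.space.death_indices:
            if self.matrix[i, i] != 1.0:
                raise InputError("TransitionModel: death states must be absorbing")
        return self

    def to_frame(self) -> pd.DataFrame:
        labels = self.space.labels()
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def _event_destination(space: StateSpace, state: HealthState, event: Event) -> int:
    if event is Event.CHD_DEATH:
        return space.idx(CHD_DEATH)
    if event is Event.IS_DEATH:
        return space.idx(IS_DEATH)
    return space.idx(acute_state(event, state.memory))


def _no_event_successor(space: StateSpace, state: HealthState) -> int:
    if state.is_acute:
        return space.idx(chronic_state(state.memory))
    return space.idx(state)


def _state_revasc_rate(
    state: HealthState, rates: AnnualEventRates, mult: Dict[str, float]
) -> float:
    """Annual revascularisation rate incident on a state's occupancy.

    Applies to ECVD, acute-MI and post-MI occupancy; memory-carrying states
    take the highest applicable member rate (maximum-risk rule).  The
    treatment effect reduces the ECVD/post-MI rates but not the acute-MI
    rate.
    """
    if state.kind is Kind.ACUTE_MI:
        return rates.revascularisation.get("acute_mi", 0.0) * mult["revasc_acute_mi"]
    candidates = []
    if Flag.ECVD in state.memory:
        candidates.append(rates.revascularisation.get("ecvd", 0.0) * mult["revasc_chronic"])
    if Flag.POST_MI in state.memory:
        candidates.append(
            rates.revascularisation.get("post_mi", 0.0) * mult["revasc_chronic"]
        )
    return max(candidates, default=0.0)


def build_cycle_core(
    space: StateSpace,
    rates: AnnualEventRates,
    dist: EventDistributionTable,
    multipliers: Optional[Dict[str, float]] = None,
) -> CycleCore:
    """Assemble the age-independent cycle dynamics for one arm.

    For each alive state the any-event rate (maximum-risk rule) is decomposed
    into per-event rates by the context's event-distribution row, each scaled
    by its treatment multiplier, recombined into an any-event probability and
    split proportionally across destinations.
    """
    mult = dict(_UNIT_MULTIPLIERS) if multipliers is None else dict(multipliers)
    n = space.n
    cond = np.zeros((n, n))
    event_cond = np.zeros((n, len(EVENT_ORDER)))
    revasc = np.zeros(n)

    for i, s in enumerate(space):
        if s.is_death:
            cond[i, i] = 1.0
            continue
        any_rate = rates.any_event_rate(s)
        shares, cerebro = dist.row(s.memory, rates.state_rates)
        # per-event annual rates after treatment scaling
        r = {
            Event.MI: any_rate * shares[0] * mult["mi"],
            Event.IS: any_rate * shares[1] * mult["is"],
            Event.HF: any_rate * shares[2] * mult["hf"],
            Event.CHD_DEATH: any_rate * shares[3] * (1.0 - cerebro) * mult["chd_death"],
            Event.IS_DEATH: any_rate * shares[3] * cerebro * mult["is_death"],
        }
        total = sum(r.values())
        p_any = annual_rate_to_prob(total)
        if total > 0:
            for k, ev in enumerate(EVENT_ORDER):
                p_ev = p_any * r[ev] / total
                if p_ev == 0.0:
                    continue
                event_cond[i, k] = p_ev
                cond[i, _event_destination(space, s, ev)] += p_ev
        cond[i, _no_event_successor(space, s)] += 1.0 - p_any
        revasc[i] = _state_revasc_rate(s, rates, mult)

    return CycleCore(space, cond, event_cond, revasc)


def apply_mortality(core: CycleCore, q_noncvd: float) -> TransitionModel:
    """Combine the conditional cycle dynamics with a non-CVD death probability."""
    if not 0.0 <= q_noncvd <= 1.0:
        raise InputError(f"non-CVD death probability {q_noncvd} outside [0, 1]")
    space = core.space
    matrix = core.conditional.copy()
    alive = list(space.alive_indices)
    matrix[alive, :] *= 1.0 - q_noncvd
    matrix[alive, space.idx(NON_CVD_DEATH)] += q_noncvd
    event_probs = core.event_cond.copy()
    event_probs[alive, :] *= 1.0 - q_noncvd
    return TransitionModel(space, matrix, event_probs, core.revasc_rates.copy()).validate()


def build_transition_matrix(
    space: StateSpace,
    rates: AnnualEventRates,
    dist: EventDistributionTable,
    life: LifeTable,
    age: float,
    female_frac: float,
    *,
    multipliers: Optional[Dict[str, float]] = None,
    mortality_convention: str = "cause_deleted",
) -> TransitionModel:
    """One cycle's transition matrix at a given cohort age."""
    q = life.noncvd_q(age, female_frac, mortality_convention)
    return apply_mortality(build_cycle_core(space, rates, dist, multipliers), q)


# --------------------------------------------------------------------------
# cohort trace
# --------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Occupancy and incidence of a cohort stepped through per-cycle models.

    ``occupancy`` has one row per cycle boundary (row 0 is the entry
    distribution); ``incidence`` gives new events per cycle by type;
    ``person_time`` is trapezoid-corrected alive person-time per cycle.
    """

    space: StateSpace
    occupancy: np.ndarray  # (T+1, n)
    incidence: Dict[Event, np.ndarray]  # each (T,)
    revascularisations: np.ndarray  # (T,)
    person_time: np.ndarray  # (T,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive_mass(self) -> np.ndarray:
        alive = list(self.space.alive_indices)
        return self.occupancy[:, alive].sum(axis=1)

    def validate(self) -> "CohortTrace":
        sums = self.occupancy.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise InputError("CohortTrace: occupancy row does not sum to 1")
        dead = self.occupancy[:, list(self.space.death_indices)].sum(axis=1)
        if (np.diff(dead) < -1e-12).any():
            raise InputError("CohortTrace: death occupancy decreased")
        return self

    def state_person_time(self) -> np.ndarray:
        """Trapezoid per-state person-time, shape (T, n)."""
        return 0.5 * (self.occupancy[:-1] + self.occupancy[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, columns=self.space.labels()).rename_axis(
            "cycle"
        )

    def to_csv(self, path) -> None:
        self.to_frame().reset_index().melt(
            id_vars="cycle", var_name="state", value_name="occupancy"
        ).to_csv(path, index=False)


def run_trace(
    models: Sequence[TransitionModel],
    initial: np.ndarray,
    *,
    stop_alive: float = 1e-6,
) -> CohortTrace:
    """Propagate a cohort through per-cycle transition models.

    Stops early once the alive mass falls below ``stop_alive``.  Person-time
    in cycle t is the mean of start- and end-of-cycle alive occupancy
    (half-cycle correction); revascularisations accrue as rate times
    trapezoid occupancy of the incident states.
    """
    if not models:
        raise InputError("run_trace: no transition models supplied")
    space = models[0].space
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (space.n,):
        raise InputError("run_trace: initial distribution has wrong length")
    if abs(initial.sum() - 1.0) > 1e-9 or (initial < 0).any():
        raise InputError("run_trace: initial distribution is not a probability vector")

    alive = list(space.alive_indices)
    occ = [initial]
    inc = {ev: [] for ev in EVENT_ORDER}
    revasc, ptime = [], []
    for model in models:
        model.validate()
        prev = occ[-1]
        nxt = prev @ model.matrix
        occ.append(nxt)
        flows = prev @ model.event_probs
        for k, ev in enumerate(EVENT_ORDER):
            inc[ev].append(flows[k])
        trap = 0.5 * (prev + nxt)
        revasc.append(float(trap @ model.revasc_rates))
        ptime.append(float(trap[alive].sum()))
        if nxt[alive].sum() < stop_alive:
            break

    trace = CohortTrace(
        space,
        np.vstack(occ),
        {ev: np.asarray(v) for ev, v in inc.items()},
        np.asarray(revasc),
        np.asarray(ptime),
    )
    return trace.validate()
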