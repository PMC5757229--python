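"""Health-state algebra for the cardiovascular Markov model.

The model distinguishes eleven base health states -- no CVD, established CVD
(ECVD), acute myocardial infarction (MI), acute ischaemic stroke (IS), acute
heart failure (HF), the three corresponding post-event states, CHD death, IS
death and non-CVD death -- plus composite chronic states that retain memory of
two or more prior event types.  Composites transition at the highest risk of
their member states and are costed at the highest member cost.

Acute states carry the full chronic-memory set they will deposit into, so a
patient with, say, a prior stroke who suffers an MI spends one cycle in an
acute-MI state remembering the stroke and then settles in the
{post-MI, post-IS} composite.
"""
from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Tuple


class Flag(str, enum.Enum):
    """Chronic memory flag deposited by a CVD event (or carried from entry)."""

    ECVD = "ecvd"
    POST_MI = "post_mi"
    POST_IS = "post_is"
    POST_HF = "post_hf"


#: Canonical ordering of chronic flags, used for stable state enumeration.
FLAG_ORDER: Tuple[Flag, ...] = (Flag.ECVD, Flag.POST_MI, Flag.POST_IS, Flag.POST_HF)


class Kind(str, enum.Enum):
    NO_CVD = "no_cvd"
    ECVD = "ecvd"
    ACUTE_MI = "acute_mi"
    ACUTE_IS = "acute_is"
    ACUTE_HF = "acute_hf"
    POST_MI = "post_mi"
    POST_IS = "post_is"
    POST_HF = "post_hf"
    COMPOSITE = "composite"
    CHD_DEATH = "chd_death"
    IS_DEATH = "is_death"
    NON_CVD_DEATH = "non_cvd_death"


DEATH_KINDS = frozenset({Kind.CHD_DEATH, Kind.IS_DEATH, Kind.NON_CVD_DEATH})
ACUTE_KINDS = frozenset({Kind.ACUTE_MI, Kind.ACUTE_IS, Kind.ACUTE_HF})
CHRONIC_KINDS = frozenset(
    {Kind.ECVD, Kind.POST_MI, Kind.POST_IS, Kind.POST_HF, Kind.COMPOSITE}
)


class Event(str, enum.Enum):
    """A CVD event occurring within one annual cycle."""

    MI = "mi"
    IS = "is"
    HF = "hf"
    CHD_DEATH = "chd_death"
    IS_DEATH = "is_death"


EVENT_ORDER: Tuple[Event, ...] = (
    Event.MI,
    Event.IS,
    Event.HF,
    Event.CHD_DEATH,
    Event.IS_DEATH,
)

#: Acute destination state kind for each non-fatal event.
ACUTE_KIND_FOR_EVENT = {
    Event.MI: Kind.ACUTE_MI,
    Event.IS: Kind.ACUTE_IS,
    Event.HF: Kind.ACUTE_HF,
}

#: The memory flag an acute state deposits into its chronic successor.
DEPOSIT_FLAG = {
    Kind.ACUTE_MI: Flag.POST_MI,
    Kind.ACUTE_IS: Flag.POST_IS,
    Kind.ACUTE_HF: Flag.POST_HF,
}

_SINGLETON_KIND = {
    Flag.ECVD: Kind.ECVD,
    Flag.POST_MI: Kind.POST_MI,
    Flag.POST_IS: Kind.POST_IS,
    Flag.POST_HF: Kind.POST_HF,
}


def _flag_key(memory: Iterable[Flag]) -> Tuple[Flag, ...]:
    return tuple(sorted(memory, key=FLAG_ORDER.index))


@dataclass(frozen=True)
class HealthState:
    """A single Markov health state.

    ``memory`` is the set of chronic flags the patient carries.  Death states
    have empty memory; acute states carry the memory they will deposit into
    (their own flag plus any pre-existing flags).
    """

    kind: Kind
    memory: FrozenSet[Flag] = frozenset()

    def __post_init__(self) -> None:
        if self.kind in DEATH_KINDS and self.memory:
            raise ValueError(f"death state {self.kind.value} must have empty memory")
        if self.kind in ACUTE_KINDS and DEPOSIT_FLAG[self.kind] not in self.memory:
            raise ValueError(
                f"acute state {self.kind.value} must carry its deposit flag"
            )

    @property
    def is_death(self) -> bool:
        return self.kind in DEATH_KINDS

    @property
    def is_acute(self) -> bool:
        return self.kind in ACUTE_KINDS

    @property
    def is_chronic(self) -> bool:
        return self.kind in CHRONIC_KINDS

    @property
    def is_composite(self) -> bool:
        return self.kind is Kind.COMPOSITE

    @property
    def label(self) -> str:
        flags = "+".join(f.value for f in _flag_key(self.memory))
        if self.kind is Kind.COMPOSITE:
            return f"composite[{flags}]"
        if self.is_acute and len(self.memory) > 1:
            return f"{self.kind.value}[{flags}]"
        return self.kind.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def chronic_state(memory: Iterable[Flag]) -> HealthState:
    """The chronic state representing a given non-empty memory set."""
    mem = frozenset(memory)
    if not mem:
        raise ValueError("chronic state requires at least one memory flag")
    if len(mem) == 1:
        (flag,) = mem
        return HealthState(_SINGLETON_KIND[flag], mem)
    return HealthState(Kind.COMPOSITE, mem)


def acute_state(event: Event, prior_memory: Iterable[Flag]) -> HealthState:
    """The acute state entered when ``event`` strikes a patient with
    ``prior_memory``; it carries the merged memory it will deposit."""
    kind = ACUTE_KIND_FOR_EVENT[event]
    mem = frozenset(prior_memory) | {DEPOSIT_FLAG[kind]}
    return HealthState(kind, mem)


# --- state space -----------------------------------------------------------

NO_CVD = HealthState(Kind.NO_CVD)
CHD_DEATH = HealthState(Kind.CHD_DEATH)
IS_DEATH = HealthState(Kind.IS_DEATH)
NON_CVD_DEATH = HealthState(Kind.NON_CVD_DEATH)


def _memory_subsets(min_size: int, max_size: int) -> Iterable[FrozenSet[Flag]]:
    for size in range(min_size, max_size + 1):
        for combo in itertools.combinations(FLAG_ORDER, size):
            yield frozenset(combo)


def base_states() -> Tuple[HealthState, ...]:
    """The eleven base states in presentation order."""
    return (
        NO_CVD,
        chronic_state({Flag.ECVD}),
        acute_state(Event.MI, ()),
        acute_state(Event.IS, ()),
        acute_state(Event.HF, ()),
        chronic_state({Flag.POST_MI}),
        chronic_state({Flag.POST_IS}),
        chronic_state({Flag.POST_HF}),
        CHD_DEATH,
        IS_DEATH,
        NON_CVD_DEATH,
    )


@dataclass(frozen=True)
class StateSpace:
    """Ordered, indexed collection of all model states."""

    states: Tuple[HealthState, ...]
    index: Mapping[HealthState, int] = field(hash=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states in state space")
        object.__setattr__(
            self, "index", {s: i for i, s in enumerate(self.states)}
        )

    @property
    def n(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i: int) -> HealthState:
        return self.states[i]

    def idx(self, state: HealthState) -> int:
        return self.index[state]

    @property
    def alive_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if not s.is_death)

    @property
    def death_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if s.is_death)

    @property
    def composite_states(self) -> Tuple[HealthState, ...]:
        return tuple(s for s in self.states if s.is_composite)

    def labels(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.states)


def enumerate_states() -> StateSpace:
    """Enumerate the full state space in a stable, deterministic order.

    Layout: the 11 base states first, then the 11 chronic composites
    (size >= 2 memory subsets of the four chronic flags), then the acute
    states carrying additional memory beyond their own deposit flag.
    """
    states = list(base_states())
    for mem in _memory_subsets(2, len(FLAG_ORDER)):
        states.append(HealthState(Kind.COMPOSITE, mem))
    for ev in (Event.MI, Event.IS, Event.HF):
        kind = ACUTE_KIND_FOR_EVENT[ev]
        own = DEPOSIT_FLAG[kind]
        others = [f for f in FLAG_ORDER if f is not own]
        for extra in _memory_subsets_of(others):
            if extra:
                states.append(HealthState(kind, frozenset(extra) | {own}))
    return StateSpace(tuple(states))


def _memory_subsets_of(flags) -> Iterable[Tuple[Flag, ...]]:
    for size in range(len(flags) + 1):
        yield from itertools.combinations(flags, size)


def composite_transition_rate(
    composite: HealthState,
    event: Event,
    per_event_rates: Mapping[Flag, Mapping[Event, float]],
) -> float:
    """Event-specific transition rate of a composite state.

    Applies the maximum-risk rule: the composite's rate for ``event`` is the
    highest of the event-specific rates of the chronic states it remembers.
    """
    if len(composite.memory) < 2:
        raise ValueError("composite_transition_rate requires memory of size >= 2")
    if not isinstance(event, Event):
        raise KeyError(f"unknown event {event!r}")
    return max(per_event_rates[flag][event] for flag in composite.memory)
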