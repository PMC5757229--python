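"""Cohort definition and synthesis of under-published model inputs.

The modelled population is an adult heterozygous familial
hypercholesterolaemia (HeFH) cohort with fasting LDL-C of at least 100 mg/dL,
described at its mean covariate values.  Several inputs the model needs are
not published at full precision anywhere (national life tables with a
cardiovascular cause decomposition, the fitted event-type distribution
conditional on prior events, risk-equation coefficients, drug prices); this
module builds deterministic synthetic stand-ins for them so the whole
pipeline runs self-contained, and reads/writes the same objects from plain
CSV so real tables can be dropped in.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .states import FLAG_ORDER, Flag

#: Unit conversion for LDL-C: 1 mmol/L of cholesterol = 38.67 mg/dL.
MGDL_PER_MMOL = 38.67


class InputError(ValueError):
    """Raised when a model input violates one of its invariants."""


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------


@dataclass
class InitialStateDistribution:
    """Entry distribution over health states.

    ``no_cvd``/``ecvd``/``post_event`` partition the whole cohort;
    ``sp_split`` gives the distribution of the secondary-prevention (SP)
    subcohort over its entry states and must sum to 1.  ``composite_split``
    optionally distributes the SP "composite" share over specific memory
    pairs; when absent, pair weights proportional to the product of the
    singleton shares are used.
    """

    no_cvd: float = 0.617
    ecvd: float = 0.234
    post_event: float = 0.149
    sp_split: Dict[str, float] = field(
        default_factory=lambda: {
            "ecvd": 0.6111,
            "post_mi": 0.2540,
            "post_is": 0.0238,
            "post_hf": 0.0079,
            "composite": 0.1032,
        }
    )

    def validate(self) -> "InitialStateDistribution":
        total = self.no_cvd + self.ecvd + self.post_event
        if abs(total - 1.0) > 1e-6:
            raise InputError(
                f"InitialStateDistribution: no_cvd + ecvd + post_event = {total:.6f}, expected 1"
            )
        sp_total = sum(self.sp_split.values())
        if abs(sp_total - 1.0) > 1e-6:
            raise InputError(
                f"InitialStateDistribution: sp_split sums to {sp_total:.6f}, expected 1"
            )
        if any(v < 0 for v in self.sp_split.values()):
            raise InputError("InitialStateDistribution: negative sp_split share")
        return self

    def composite_pair_weights(self) -> Dict[FrozenSet[Flag], float]:
        """Allocation of the SP composite share over memory pairs.

        Weights are proportional to the product of the singleton SP shares,
        so the {ECVD, post-MI} pair dominates, mirroring the relative
        frequency of the underlying event histories.
        """
        singles = {
            Flag.ECVD: self.sp_split["ecvd"],
            Flag.POST_MI: self.sp_split["post_mi"],
            Flag.POST_IS: self.sp_split["post_is"],
            Flag.POST_HF: self.sp_split["post_hf"],
        }
        weights = {
            frozenset(pair): singles[pair[0]] * singles[pair[1]]
            for pair in itertools.combinations(FLAG_ORDER, 2)
        }
        total = sum(weights.values())
        return {k: v / total for k, v in weights.items()}


@dataclass
class CohortProfile:
    """Baseline characteristics of the modelled HeFH cohort (trial means).

    Units: ages in years, pressures in mmHg, lipids in mg/dL, all ``*_frac``
    fields are proportions in [0, 1].
    """

    age_mean: float = 51.16
    age_sd: float = 12.60
    female_frac: float = 0.4225
    smoking_frac: float = 0.1581
    t2dm_frac: float = 0.0729
    htn_therapy_frac: float = 0.3252
    asa_frac: float = 0.3860
    sbp_mean: float = 125.73
    sbp_sd: float = 13.63
    low_bmi_frac: float = 0.0182  # BMI < 20 kg/m^2
    ldl_mean: float = 155.46
    ldl_sd: float = 44.93
    tc_mean: float = 231.56
    hdl_mean: float = 51.13
    vascular_beds: float = 1.21
    afib_frac: float = 0.1170
    prior_cvd_frac: float = 0.3830
    initial_state_dist: InitialStateDistribution = field(
        default_factory=InitialStateDistribution
    )

    _FRACTIONS = (
        "female_frac",
        "smoking_frac",
        "t2dm_frac",
        "htn_therapy_frac",
        "asa_frac",
        "low_bmi_frac",
        "afib_frac",
        "prior_cvd_frac",
    )

    def validate(self) -> "CohortProfile":
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"CohortProfile: {name} = {v} outside [0, 1]")
        if self.ldl_mean < 100.0:
            raise InputError(
                f"CohortProfile: ldl_mean = {self.ldl_mean} mg/dL below the "
                "modelled population restriction of 100 mg/dL"
            )
        self.initial_state_dist.validate()
        if abs(self.prior_cvd_frac - (1.0 - self.initial_state_dist.no_cvd)) > 1e-2:
            raise InputError(
                "CohortProfile: prior_cvd_frac inconsistent with the no-CVD entry share"
            )
        return self


def default_cohort() -> CohortProfile:
    """The trial-reported HeFH cohort: mean age 51.16 y, 42.25% female, mean
    LDL-C 155.46 mg/dL, 38.30% with a previous CVD event."""
    return CohortProfile()


# --------------------------------------------------------------------------
# Life table
# --------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Annual all-cause death probabilities with a CVD cause decomposition.

    ``frame`` has columns ``age`` (integer years), ``sex`` ("female"/"male"),
    ``q_all`` (annual all-cause death probability) and ``cvd_death_frac``
    (share of deaths attributable to ischaemic heart disease, ICD I20-I25,
    and cerebrovascular disease, ICD I60-I69).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age", "sex", "q_all", "cvd_death_frac"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"LifeTable: missing columns {sorted(missing)}")
        self.frame = self.frame.sort_values(["sex", "age"]).reset_index(drop=True)
        self._by_sex = {
            sex: grp.set_index("age")[["q_all", "cvd_death_frac"]]
            for sex, grp in self.frame.groupby("sex")
        }

    def validate(self) -> "LifeTable":
        q = self.frame["q_all"].to_numpy()
        f = self.frame["cvd_death_frac"].to_numpy()
        if ((q < 0) | (q > 1)).any():
            raise InputError("LifeTable: q_all outside [0, 1]")
        if ((f < 0) | (f > 1)).any():
            raise InputError("LifeTable: cvd_death_frac outside [0, 1]")
        return self

    @property
    def max_age(self) -> int:
        return int(self.frame["age"].max())

    def _lookup(self, age: float, sex: str, col: str) -> float:
        table = self._by_sex[sex]
        a = int(min(max(np.floor(age), table.index.min()), table.index.max()))
        return float(table.loc[a, col])

    def q_all(self, age: float, sex: str) -> float:
        return self._lookup(age, sex, "q_all")

    def cvd_death_frac(self, age: float, sex: str) -> float:
        return self._lookup(age, sex, "cvd_death_frac")

    def weighted_q_all(self, age: float, female_frac: float) -> float:
        """Cohort-level all-cause death probability, sex-weighted."""
        return female_frac * self.q_all(age, "female") + (1.0 - female_frac) * self.q_all(
            age, "male"
        )

    def noncvd_q(
        self, age: float, female_frac: float, convention: str = "cause_deleted"
    ) -> float:
        """Annual probability of death from causes other than CVD.

        ``cause_deleted`` uses the competing-risk convention
        ``1 - (1 - q_all)**(1 - frac)`` which stays a valid probability at any
        q_all; ``simple`` is the naive subtraction ``q_all * (1 - frac)``.
        """
        q = self.weighted_q_all(age, female_frac)
        frac = female_frac * self.cvd_death_frac(age, "female") + (
            1.0 - female_frac
        ) * self.cvd_death_frac(age, "male")
        if convention == "cause_deleted":
            return 1.0 - (1.0 - q) ** (1.0 - frac)
        if convention == "simple":
            return q * (1.0 - frac)
        raise InputError(f"LifeTable: unknown mortality convention {convention!r}")

    # -- IO ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        # %.17g keeps float round-trips through text exact
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path, float_precision="round_trip")).validate()

    def to_records(self):
        return self.frame.to_dict(orient="records")

    @classmethod
    def from_records(cls, records) -> "LifeTable":
        return cls(pd.DataFrame.from_records(records)).validate()

    def __eq__(self, other) -> bool:
        return isinstance(other, LifeTable) and self.frame.equals(other.frame)


def default_cvd_death_fraction(age: float) -> float:
    """Synthetic share of deaths from IHD + cerebrovascular disease by age.

    A logistic ramp from ~6% of deaths in early adulthood towards ~55% at
    very old ages, shaped after the dominance of circulatory mortality in
    Eastern-European cause-of-death statistics.
    """
    return 0.05 + 0.50 / (1.0 + np.exp(-(age - 70.0) / 10.0))


def generate_life_table(
    makeham_a: float,
    gompertz_b: float,
    gompertz_c: float,
    max_age: int = 110,
    cvd_frac_curve: Union[float, Callable[[float], float], None] = None,
    *,
    female_factor: float = 1.0,
    male_factor: float = 1.0,
    clip: bool = True,
) -> LifeTable:
    """Deterministic Gompertz-Makeham life table for both sexes.

    The all-cause hazard at integer age ``x`` is
    ``factor * (a + b * c**x)`` with a sex-specific proportional ``factor``,
    giving ``q_all(x) = 1 - exp(-hazard)``.  ``cvd_frac_curve`` may be a
    scalar or a function of age; values are clipped to [0, 1].
    """
    if cvd_frac_curve is None:
        cvd_frac_curve = default_cvd_death_fraction
    ages = np.arange(0, max_age + 1)
    rows = []
    for sex, factor in (("female", female_factor), ("male", male_factor)):
        hazard = factor * (makeham_a + gompertz_b * np.power(gompertz_c, ages.astype(float)))
        if (hazard < 0).any():
            if not clip:
                raise InputError("generate_life_table: negative hazard from parameters")
            hazard = np.clip(hazard, 0.0, None)
        q = 1.0 - np.exp(-hazard)
        if callable(cvd_frac_curve):
            frac = np.array([cvd_frac_curve(a) for a in ages], dtype=float)
        else:
            frac = np.full(ages.shape, float(cvd_frac_curve))
        frac = np.clip(frac, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {"age": ages, "sex": sex, "q_all": q, "cvd_death_frac": frac}
            )
        )
    return LifeTable(pd.concat(rows, ignore_index=True)).validate()


def default_life_table() -> LifeTable:
    """Synthetic stand-in for national life tables by age and sex.

    Gompertz-Makeham parameters and sex factors were chosen once to give
    mid-life and old-age death probabilities of a plausible Eastern-European
    magnitude (e.g. roughly 0.5% per year around age 51, 6-9% around age 85).
    """
    return generate_life_table(
        5.0e-4,
        3.2e-5,
        1.094,
        max_age=110,
        cvd_frac_curve=default_cvd_death_fraction,
        female_factor=0.7,
        male_factor=1.3,
    )


# --------------------------------------------------------------------------
# Event-type distribution
# --------------------------------------------------------------------------

#: Columns of an event-distribution row: shares of the next CVD event.
EVENT_SHARE_COLS: Tuple[str, ...] = ("mi", "is", "hf", "cv_death")

ContextKey = Tuple[str, ...]


def context_key(memory: FrozenSet[Flag]) -> ContextKey:
    """Stable lookup key for a prior-event context (empty = no prior event)."""
    return tuple(f.value for f in sorted(memory, key=FLAG_ORDER.index))


@dataclass
class EventDistributionTable:
    """Conditional distribution of the next CVD event given prior events.

    For each prior-event context (no CVD, ECVD, post-MI, post-IS, post-HF and
    each composite) a row gives the shares of the next event among MI, IS, HF
    and CV death, plus the fraction of CV deaths that are cerebrovascular
    (counted as IS death; the remainder as CHD death).
    """

    shares: Dict[ContextKey, np.ndarray]
    cerebro_frac: Dict[ContextKey, float]

    def validate(self) -> "EventDistributionTable":
        for key, row in self.shares.items():
            row = np.asarray(row, dtype=float)
            if (row < 0).any():
                raise InputError(f"EventDistributionTable: negative share in row {key}")
            if abs(row.sum() - 1.0) > 1e-9:
                raise InputError(
                    f"EventDistributionTable: row {key} sums to {row.sum():.12f}"
                )
            c = self.cerebro_frac.get(key)
            if c is None or not 0.0 <= c <= 1.0:
                raise InputError(
                    f"EventDistributionTable: cerebrovascular fraction for {key} "
                    f"missing or outside [0, 1]"
                )
        return self

    def normalised(self) -> "EventDistributionTable":
        shares = {}
        for k, v in self.shares.items():
            row = np.asarray(v, dtype=float)
            # idempotent: rows already summing to 1 are kept bit-identical
            shares[k] = row if abs(row.sum() - 1.0) <= 1e-12 else row / row.sum()
        return EventDistributionTable(shares, dict(self.cerebro_frac))

    def row(
        self,
        memory: FrozenSet[Flag],
        state_rates: Optional[Mapping[str, float]] = None,
    ) -> Tuple[np.ndarray, float]:
        """Shares and cerebrovascular fraction for a prior-event context.

        Falls back, for contexts without their own row, to the member flag
        with the highest any-event rate (consistent with the composite
        maximum-risk rule); ``state_rates`` supplies those rates.
        """
        key = context_key(memory)
        if key in self.shares:
            return np.asarray(self.shares[key], dtype=float), self.cerebro_frac[key]
        if not memory:
            raise InputError("EventDistributionTable: no row for the no-prior-event context")
        if state_rates is None:
            raise InputError(
                f"EventDistributionTable: no row for context {key} and no rates "
                "given for the fallback lookup"
            )
        best = max(memory, key=lambda f: state_rates[f.value])
        bkey = context_key(frozenset({best}))
        if bkey not in self.shares:
            raise InputError(f"EventDistributionTable: no row for context {key} or {bkey}")
        return np.asarray(self.shares[bkey], dtype=float), self.cerebro_frac[bkey]

    # -- IO ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.shares, key=lambda k: (len(k), k)):
            rec = {"context": "+".join(key) if key else "none"}
            rec.update(dict(zip(EVENT_SHARE_COLS, np.asarray(self.shares[key], float))))
            rec["cv_death_cerebrovascular_frac"] = self.cerebro_frac[key]
            rows.append(rec)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventDistributionTable":
        shares, cerebro = {}, {}
        for _, rec in frame.iterrows():
            ctx = rec["context"]
            key: ContextKey = () if ctx == "none" else tuple(ctx.split("+"))
            shares[key] = np.array([rec[c] for c in EVENT_SHARE_COLS], dtype=float)
            cerebro[key] = float(rec["cv_death_cerebrovascular_frac"])
        return cls(shares, cerebro).validate()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "EventDistributionTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventDistributionTable):
            return False
        if set(self.shares) != set(other.shares):
            return False
        return all(
            np.array_equal(self.shares[k], other.shares[k])
            and self.cerebro_frac[k] == other.cerebro_frac[k]
            for k in self.shares
        )


# Template shares (MI, IS, HF, CV death) per base context and the fraction of
# CV deaths that are cerebrovascular.  Magnitudes shaped after published
# secondary-prevention event mixes: recurrent events concentrate on the prior
# event type, CV death claims roughly a fifth to a quarter of events.
_EVENT_TEMPLATES: Dict[ContextKey, Tuple[Tuple[float, float, float, float], float]] = {
    (): ((0.50, 0.11, 0.15, 0.24), 0.18),
    ("ecvd",): ((0.52, 0.12, 0.13, 0.23), 0.20),
    ("post_mi",): ((0.62, 0.07, 0.11, 0.20), 0.10),
    ("post_is",): ((0.24, 0.45, 0.08, 0.23), 0.45),
    ("post_hf",): ((0.27, 0.09, 0.38, 0.26), 0.15),
}


def generate_event_distribution(seed: int) -> EventDistributionTable:
    """Reproducible synthetic event-type distribution table.

    Stand-in for the fitted multinomial shares of the next event conditional
    on prior events.  Base contexts get template shares with small seeded
    lognormal jitter (sigma 0.03), preserving the structural feature that a
    prior MI weights MI higher and a prior stroke weights stroke higher.
    Composite contexts take the renormalised element-wise maximum of their
    member rows, matching the composite maximum-risk convention.
    """
    rng = np.random.default_rng(seed)
    shares: Dict[ContextKey, np.ndarray] = {}
    cerebro: Dict[ContextKey, float] = {}
    for key, (tmpl, cfrac) in _EVENT_TEMPLATES.items():
        row = np.asarray(tmpl, dtype=float) * np.exp(rng.normal(0.0, 0.03, size=4))
        shares[key] = row / row.sum()
        cerebro[key] = float(np.clip(cfrac * np.exp(rng.normal(0.0, 0.10)), 0.01, 0.90))
    for size in range(2, len(FLAG_ORDER) + 1):
        for combo in itertools.combinations(FLAG_ORDER, size):
            key = context_key(frozenset(combo))
            member_keys = [context_key(frozenset({f})) for f in combo]
            stacked = np.stack([shares[mk] for mk in member_keys])
            row = stacked.max(axis=0)
            shares[key] = row / row.sum()
            cv_weights = np.array([shares[mk][3] for mk in member_keys])
            cvals = np.array([cerebro[mk] for mk in member_keys])
            cerebro[key] = float((cv_weights * cvals).sum() / cv_weights.sum())
    return EventDistributionTable(shares, cerebro).validate()
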