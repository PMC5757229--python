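"""Individual-level microsimulation oracle.

Steps a population of simulated individuals through the same per-cycle
transition matrices as the cohort trace.  This is a validation device: by the
law of large numbers its state-occupancy proportions must agree with the
deterministic cohort trace within Monte Carlo error.  It is not used for
production results.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .markov import TransitionModel


def microsimulate(
    models: Sequence[TransitionModel],
    initial: np.ndarray,
    n_individuals: int,
    seed: int,
) -> np.ndarray:
    """Simulate ``n_individuals`` and return occupancy proportions.

    Returns an array of shape ``(len(models) + 1, n_states)`` whose rows are
    the proportions of individuals in each state at each cycle boundary,
    directly comparable with :class:`~etpymodel.markov.CohortTrace.occupancy`.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    space = models[0].space
    counts = rng.multinomial(n_individuals, np.asarray(initial, dtype=float))
    history = [counts.copy()]
    for model in models:
        nxt = np.zeros(space.n, dtype=np.int64)
        for i in np.nonzero(counts)[0]:
            row = np.clip(model.matrix[i], 0.0, None)
            nxt += rng.multinomial(counts[i], row / row.sum())
        counts = nxt
        history.append(counts.copy())
    return np.vstack(history) / float(n_individuals)


def occupancy_mc_se(occupancy: np.ndarray, n_individuals: int) -> np.ndarray:
    """Binomial Monte Carlo standard error for each trace occupancy entry."""
    p = np.clip(occupancy, 0.0, 1.0)
    return np.sqrt(p * (1.0 - p) / float(n_individuals))
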