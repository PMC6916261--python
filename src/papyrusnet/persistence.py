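"""Steady-state persistence of a two-state occupancy chain, and patch
classification into resistance/resilience categories.

Each patch follows a yearly Markov chain: an occupied patch keeps its
population with annual survival probability S (its *resistance*); an empty
patch is colonized with annual probability C (its *resilience*).  The
long-run probability P of finding the patch occupied has closed forms:

    no rescue:   P = C / (1 - S + C)
    with rescue: P = C / (1 - S + S*C)

The rescue variant lets a population that went extinct this year be
re-established by colonists within the same year (extinction followed by
same-year colonization with probability (1-S)*C), which raises P; it can
push P above 0.5 even when S + C < 1.  Without rescue, P = 0.5 exactly on
the line S + C = 1.

Patches are classified against survival/colonization thresholds (default
0.5 on each axis, a value equal to the threshold counting as high):
high/high -> resistant_and_resilient, high S only -> resistant_only,
high C only -> resilient_only, neither -> marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np


class Category(str, Enum):
    RESISTANT_AND_RESILIENT = "resistant_and_resilient"  # purple
    RESISTANT_ONLY = "resistant_only"  # red
    RESILIENT_ONLY = "resilient_only"  # blue
    MARGINAL = "marginal"  # black


#: Returned where the steady state is indeterminate (S = 1, C = 0: the
#: chain has two absorbing classes and the limit depends on the start).
INDETERMINATE = float("nan")


def _check_probs(S: float, C: float) -> None:
    if not (0 <= S <= 1 and 0 <= C <= 1):
        raise ValueError(f"S and C must be probabilities, got S={S}, C={C}")


def steady_state_no_rescue(S: float, C: float) -> float:
    """P = C/(1-S+C): stationary occupancy without same-year rescue."""
    _check_probs(S, C)
    denom = 1.0 - S + C
    if denom == 0.0:
        import warnings

        warnings.warn("S=1, C=0: steady state indeterminate (defined by limit)")
        return INDETERMINATE
    return C / denom


def steady_state_rescue(S: float, C: float) -> float:
    """P = C/(1-S+S*C): stationary occupancy with same-year rescue."""
    _check_probs(S, C)
    denom = 1.0 - S + S * C
    if denom == 0.0:
        import warnings

        warnings.warn("S=1, C=0: steady state indeterminate (defined by limit)")
        return INDETERMINATE
    return C / denom


def markov_equilibrium_simulation(
    S: float,
    C: float,
    rescue: bool = False,
    steps: int = 100_000,
    burn_in: int = 1_000,
    seed: int = 0,
) -> float:
    """Empirical long-run occupancy of the per-patch chain (oracle for the
    closed forms).

    Occupied -> occupied w.p. S; in rescue mode an extinction is followed by
    a same-year colonization attempt w.p. C.  Empty -> occupied w.p. C.
    Returns the post-burn-in occupancy frequency.
    """
    _check_probs(S, C)
    if steps < 10 * burn_in:
        raise ValueError("steps must be >= 10 * burn_in")
    rng = np.random.default_rng(seed)
    u = rng.random((steps, 2))
    occupied = u[0, 0] < 0.5
    count = 0
    for t in range(steps):
        if occupied:
            if u[t, 0] < S:
                occupied = True
            else:
                occupied = rescue and u[t, 1] < C
        else:
            occupied = u[t, 0] < C
        if t >= burn_in:
            count += occupied
    return count / (steps - burn_in)


def classify_patch(
    S_prob: float, C_prob: float, s_threshold: float = 0.5, c_threshold: float = 0.5
) -> Category:
    """Quadrant category of a patch from its survival and colonization
    probabilities; equality with a threshold counts as high."""
    if not (0 < s_threshold < 1 and 0 < c_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    _check_probs(S_prob, C_prob)
    s_high = S_prob >= s_threshold
    c_high = C_prob >= c_threshold
    if s_high and c_high:
        return Category.RESISTANT_AND_RESILIENT
    if s_high:
        return Category.RESISTANT_ONLY
    if c_high:
        return Category.RESILIENT_ONLY
    return Category.MARGINAL


@dataclass
class PersistenceResult:
    """Per patch, per species: turnover probabilities, both steady states
    and the quadrant category."""

    patch_id: str
    species: str
    S_prob: float
    C_prob: float
    P_no_rescue: float
    P_rescue: float
    category: Category

    @classmethod
    def from_probabilities(
        cls,
        patch_id: str,
        species: str,
        S_prob: float,
        C_prob: float,
        s_threshold: float = 0.5,
        c_threshold: float = 0.5,
    ) -> "PersistenceResult":
        return cls(
            patch_id=patch_id,
            species=species,
            S_prob=S_prob,
            C_prob=C_prob,
            P_no_rescue=steady_state_no_rescue(S_prob, C_prob),
            P_rescue=steady_state_rescue(S_prob, C_prob),
            category=classify_patch(S_prob, C_prob, s_threshold, c_threshold),
        )


def classify_network(
    survival_probs,
    colonization_probs,
    species: str,
    s_threshold: float = 0.5,
    c_threshold: float = 0.5,
) -> dict[str, PersistenceResult]:
    """Classify every patch appearing in both probability maps."""
    ids = sorted(set(survival_probs.keys()) & set(colonization_probs.keys()))
    return {
        pid: PersistenceResult.from_probabilities(
            pid,
            species,
            float(survival_probs[pid]),
            float(colonization_probs[pid]),
            s_threshold,
            c_threshold,
        )
        for pid in ids
    }


def results_table(results: dict[str, PersistenceResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "species": r.species,
                "S_prob": r.S_prob,
                "C_prob": r.C_prob,
                "P_no_rescue": r.P_no_rescue,
                "P_rescue": r.P_rescue,
                "category": r.category.value,
            }
            for r in results.values()
        ]
    )
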