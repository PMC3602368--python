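"""Resampling and rank tests for lost-vs-retained node comparisons.

The scenario analysis asks whether the sites a species loses under future
conditions are a random draw from the network or a biased one (e.g. toward
poorly connected sites).  The primary tool is a Monte-Carlo permutation
test: draw many same-size subsets of the pooled current nodes and compare
the observed lost-minus-retained mean difference against that null.
Mann–Whitney U and Spearman rank correlation cover the remaining
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

__all__ = [
    "Sidedness",
    "PermutationResult",
    "permutation_test",
    "mann_whitney_u",
    "spearman",
]


class Sidedness(str, Enum):
    TWO_SIDED = "two_sided"
    LOWER = "lower"
    GREATER = "greater"


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    n_permutations: int
    p_value: float
    sidedness: Sidedness
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "sidedness": self.sidedness.value,
            "seed": self.seed,
        }


def permutation_test(
    lost_values,
    retained_values,
    n_perm: int = 999,
    sidedness: Sidedness | str = Sidedness.TWO_SIDED,
    seed: int = 0,
) -> PermutationResult:
    """Subset-resampling permutation test of mean(lost) − mean(retained).

    The null is built by drawing ``n_perm`` subsets of size ``|lost|``
    without replacement from the pooled values (lost ∪ retained) and
    recomputing the mean difference between the subset and its complement.
    The p-value uses add-one smoothing, ``p = (1 + #as-or-more-extreme) /
    (n_perm + 1)``, so it can never be 0 and is floored at 1/(n_perm+1).
    """
    sidedness = Sidedness(sidedness)
    lost = np.asarray(lost_values, dtype=float)
    retained = np.asarray(retained_values, dtype=float)
    if lost.size == 0 or retained.size == 0:
        raise ValueError("both value vectors must be nonempty")
    if retained.size < lost.size:
        raise ValueError("retained group must be at least as large as the lost group")

    observed = float(lost.mean() - retained.mean())
    pool = np.concatenate([lost, retained])
    if np.ptp(pool) == 0.0:
        return PermutationResult(observed, n_perm, 1.0, sidedness, seed)

    rng = np.random.default_rng(seed)
    k, n = lost.size, pool.size
    # n_perm subsets of size k without replacement, drawn at once
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    subset_sum = pool[order[:, :k]].sum(axis=1)
    total = pool.sum()
    null = subset_sum / k - (total - subset_sum) / (n - k)

    if sidedness is Sidedness.LOWER:
        extreme = int((null <= observed).sum())
    elif sidedness is Sidedness.GREATER:
        extreme = int((null >= observed).sum())
    else:
        extreme = int((np.abs(null) >= abs(observed)).sum())
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(observed, n_perm, float(p), sidedness, seed)


# exact Mann-Whitney null is enumerated when the pair count is this small
_EXACT_PAIR_LIMIT = 400


def mann_whitney_u(a, b) -> dict:
    """Two-sided Mann–Whitney U test; reports U = min(U_a, U_b).

    Ties receive midranks.  The null distribution is enumerated exactly for
    small tie-free samples (n_a·n_b ≤ 400); otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= _EXACT_PAIR_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return {"U": u, "p_value": float(res.pvalue)}


def spearman(x, y) -> dict:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p)}
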