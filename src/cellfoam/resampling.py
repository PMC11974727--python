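"""Resampling statistics: one-tailed permutation test of the difference of
means, and percentile bootstrap confidence intervals for the mean."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["PermutationResult", "permutation_test_diff_means", "bootstrap_ci_mean"]

#: Enumerate all label splits instead of sampling when C(n1+n2, n1) is at most this.
FULL_ENUMERATION_LIMIT = 100_000


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_permutations: int
    p_value: float
    alternative: str
    seed: int | None
    exact: bool = False


def permutation_test_diff_means(x: Sequence[float], y: Sequence[float],
                                n_perm: int = 9999,
                                alternative: str = "greater",
                                seed: int | None = None,
                                method: str = "auto") -> PermutationResult:
    """One-tailed permutation test of ``mean(x) - mean(y)``.

    The direction must be stated by the caller (``greater`` or ``less``);
    it is never inferred from the data. Monte-Carlo p-values carry the +1
    correction, ``p = (1 + #extreme) / (n_perm + 1)``, so p is never 0.
    With ``method='auto'`` the test enumerates every label split exactly
    when there are at most :data:`FULL_ENUMERATION_LIMIT` of them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if method not in ("auto", "exact", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")

    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    total = math.comb(n, n1)

    if method == "exact" or (method == "auto" and total <= FULL_ENUMERATION_LIMIT):
        # sum over group-1 indices is enough: diff = s1/n1 - (S - s1)/n2
        s_all = pooled.sum()
        n2 = n - n1
        extreme = 0
        for idx in combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            stat = s1 / n1 - (s_all - s1) / n2
            if _as_extreme(stat, observed, alternative):
                extreme += 1
        return PermutationResult(observed, total, extreme / total,
                                 alternative, seed, exact=True)

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: permute each row of a tiled pool
    tiles = np.broadcast_to(pooled, (n_perm, n)).copy()
    tiles = rng.permuted(tiles, axis=1)
    stats = tiles[:, :n1].mean(axis=1) - tiles[:, n1:].mean(axis=1)
    extreme = int(np.sum(_as_extreme(stats, observed, alternative)))
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(observed, n_perm, p, alternative, seed, exact=False)


def _as_extreme(stat, observed: float, alternative: str):
    tol = 1e-12 * max(1.0, abs(observed))
    if alternative == "greater":
        return stat >= observed - tol
    return stat <= observed + tol


def bootstrap_ci_mean(values: Sequence[float], level: float = 0.99,
                      n_boot: int = 2000,
                      seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)
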