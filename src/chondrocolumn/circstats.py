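"""Statistical tests for orientation and intensity samples.

The orientation comparisons use Watson's U² two-sample test, a
nonparametric test for differences between circular distributions based
on the discrepancy of empirical cumulative fractions around the circle.
Axial data (orientations with 180° period, e.g. column orientations in
[0°, 90°]) are doubled to circular data before testing, the standard
treatment for axial samples. Significance is assessed by a seeded
permutation null — exhaustive enumeration of all label splits when the
pooled sample is small enough, random permutations otherwise — rather
than asymptotic tables, which is preferable at the small sample sizes
typical of clone-level data.

Scalar comparisons use the Wilcoxon rank-sum test; a one-sample
Kolmogorov–Smirnov normality check (against a normal law with the
sample's own mean and SD) gates the choice of the nonparametric path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AngleSample",
    "TestResult",
    "watson_u2",
    "watson_u2_statistic",
    "wilcoxon_rank_sum",
    "ks_normality",
]


@dataclass(frozen=True)
class AngleSample:
    """A sample of angles in degrees, axial (180° period) or circular."""

    values_deg: tuple
    kind: str = "axial"

    def __post_init__(self):
        if self.kind not in ("axial", "circular"):
            raise ValueError("kind must be 'axial' or 'circular'")
        vals = np.asarray(self.values_deg, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("angles must be finite")

    def as_circular_deg(self) -> np.ndarray:
        """Angles on the full circle [0°, 360°); axial data are doubled."""
        v = np.asarray(self.values_deg, dtype=float)
        if self.kind == "axial":
            return np.mod(2.0 * np.mod(v, 180.0), 360.0)
        return np.mod(v, 360.0)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    n_permutations: Optional[int] = None
    seed: Optional[int] = None
    recommendation: Optional[str] = None
    flags: list = field(default_factory=list)


def _tie_groups_last(d: np.ndarray, x_sorted: np.ndarray) -> np.ndarray:
    """Make the ECDF difference constant within tied pooled values.

    The cumulative difference is only well defined after a whole tie
    group has been counted; assigning that value to every member makes
    the statistic invariant to the arbitrary ordering inside ties
    (midrank-style convention).
    """
    out = d.copy()
    i = 0
    n = len(x_sorted)
    while i < n:
        j = i
        while j + 1 < n and x_sorted[j + 1] == x_sorted[i]:
            j += 1
        if j > i:
            out[i:j + 1] = d[j]
        i = j + 1
    return out


def watson_u2_statistic(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Two-sample Watson U² from circular samples in degrees.

    U² = (n1·n2 / N²) · Σ_k (d_k − d̄)² with d_k the difference of the
    two empirical cumulative fractions at the k-th pooled point. The
    mean-centering makes the statistic invariant to a common rotation
    of both samples (the choice of cut point on the circle).
    """
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n1), np.zeros(n2)])
    order = np.argsort(pooled, kind="stable")
    x = pooled[order]
    lab = labels[order]
    d = np.cumsum(lab) / n1 - np.cumsum(1.0 - lab) / n2
    if len(np.unique(x)) < len(x):
        d = _tie_groups_last(d, x)
    n = n1 + n2
    return float(n1 * n2 / n ** 2 * np.sum((d - d.mean()) ** 2))


@lru_cache(maxsize=8)
def _split_matrix(n1: int, n2: int) -> np.ndarray:
    """All C(N, n1) binary label assignments, one row per split."""
    n = n1 + n2
    combos = list(combinations(range(n), n1))
    mat = np.zeros((len(combos), n), dtype=float)
    for i, idx in enumerate(combos):
        mat[i, list(idx)] = 1.0
    return mat


def _u2_for_labels(x_sorted: np.ndarray, labels: np.ndarray,
                   n1: int, n2: int, tie_groups) -> np.ndarray:
    """Vectorized U² for many label assignments over one sorted pooling."""
    n = n1 + n2
    d = np.cumsum(labels, axis=1) / n1 - np.cumsum(1.0 - labels, axis=1) / n2
    if tie_groups is not None:
        for i, j in tie_groups:
            d[:, i:j + 1] = d[:, [j]]
    dc = d - d.mean(axis=1, keepdims=True)
    return n1 * n2 / n ** 2 * np.sum(dc ** 2, axis=1)


def _find_tie_groups(x_sorted: np.ndarray):
    groups = []
    i, n = 0, len(x_sorted)
    while i < n:
        j = i
        while j + 1 < n and x_sorted[j + 1] == x_sorted[i]:
            j += 1
        if j > i:
            groups.append((i, j))
        i = j + 1
    return groups or None


def watson_u2(a: AngleSample, b: AngleSample,
              n_permutations: int = 9999, seed: int = 0,
              enumeration_cap: int = 50_000) -> TestResult:
    """Watson's U² two-sample test with a permutation p-value.

    Axial samples are doubled to the circle first. The null is built by
    relabeling the pooled sample: exhaustively over all C(N, n1) splits
    when that count is at most ``enumeration_cap`` (exact p), otherwise
    ``n_permutations`` seeded random relabelings with the add-one
    correction p = (1 + #{U²* ≥ U²}) / (1 + B). Requires n ≥ 4 per
    sample; ties are handled by a midrank-style convention and flagged.
    """
    av = a.as_circular_deg()
    bv = b.as_circular_deg()
    n1, n2 = len(av), len(bv)
    if n1 < 4 or n2 < 4:
        raise ValueError("watson_u2 requires at least 4 angles per sample")
    obs = watson_u2_statistic(av, bv)

    pooled = np.sort(np.concatenate([av, bv]), kind="stable")
    tie_groups = _find_tie_groups(pooled)
    flags = ["ties_midrank"] if tie_groups else []

    from math import comb
    n_splits = comb(n1 + n2, n1)
    if n_splits <= enumeration_cap:
        labels = _split_matrix(n1, n2)
        null = _u2_for_labels(pooled, labels, n1, n2, tie_groups)
        p = float(np.mean(null >= obs - 1e-12))
        return TestResult(statistic=obs, p_value=p,
                          method="watson_u2_enumeration",
                          n1=n1, n2=n2, n_permutations=n_splits,
                          seed=None, flags=flags)

    rng = np.random.default_rng(seed)
    base = np.concatenate([np.ones(n1), np.zeros(n2)])
    labels = np.tile(base, (n_permutations, 1))
    labels = rng.permuted(labels, axis=1)
    null = _u2_for_labels(pooled, labels, n1, n2, tie_groups)
    p = float((1 + np.sum(null >= obs - 1e-12)) / (1 + n_permutations))
    return TestResult(statistic=obs, p_value=p,
                      method="watson_u2_permutation",
                      n1=n1, n2=n2, n_permutations=n_permutations,
                      seed=seed, flags=flags)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p-value for small samples without ties, normal approximation
    with midrank tie correction otherwise. A fully degenerate comparison
    (every value identical in both samples) returns p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("wilcoxon_rank_sum requires n >= 2 per sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=float(len(x) * len(y) / 2.0),
                          p_value=1.0, method="wilcoxon_rank_sum",
                          n1=len(x), n2=len(y),
                          flags=["degenerate_all_equal"])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    flags = []
    if len(np.unique(pooled)) < len(pooled):
        flags.append("ties_midrank")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method="wilcoxon_rank_sum",
                      n1=len(x), n2=len(y), flags=flags)


def ks_normality(x, alpha: float = 0.05) -> TestResult:
    """One-sample Kolmogorov–Smirnov check against a fitted normal law.

    Tests against N(mean(x), sd(x)). Because the parameters are
    estimated from the same sample the p-value is conservative
    (Lilliefors caveat, flagged). The ``recommendation`` field says
    which comparison path to take: "nonparametric" when normality is
    rejected at ``alpha``, "parametric_ok" otherwise.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("ks_normality requires n >= 5")
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        return TestResult(statistic=1.0, p_value=0.0,
                          method="ks_normality", n1=len(x),
                          recommendation="nonparametric",
                          flags=["zero_variance"])
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    rec = "nonparametric" if res.pvalue < alpha else "parametric_ok"
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method="ks_normality", n1=len(x),
                      recommendation=rec,
                      flags=["parameters_estimated_from_sample"])
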