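"""Comparison methods: univariate MWW screening with FWER corrections, and
the unbiased squared-MMD kernel two-sample permutation test.

The screening route mirrors common clinical practice: one two-sided
Mann-Whitney-Wilcoxon test per feature, then a family-wise error correction
(Bonferroni, Holm, Hochberg or Hommel).  The MMD test is the multivariate
gold-standard baseline: Gaussian kernel with the median-distance bandwidth
heuristic, unbiased U-statistic estimator of squared MMD, and a
label-permutation null with the statistic recomputed per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .datasets import FeatureTable, ParameterError
from .forest import DegenerateLabelsError

CORRECTION_METHODS = ("bonferroni", "holm", "hochberg", "hommel")
_STATSMODELS_NAMES = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
}


def univariate_screen(table: FeatureTable) -> np.ndarray:
    """Two-sided MWW p-value for each feature column.

    Constant columns get p = 1 with a warning (no rank information).
    """
    if table.n_pos == 0 or table.n_neg == 0:
        raise DegenerateLabelsError("both classes must be present")
    X = table.X
    pos = table.labels > 0
    pvals = np.empty(table.n_dims)
    for j in range(table.n_dims):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"feature column {j} is constant; p-value set to 1")
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(
            col[pos], col[~pos], alternative="two-sided"
        ).pvalue
    return pvals


def adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    """FWER-adjusted p-values (bonferroni / holm / hochberg / hommel)."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if method not in _STATSMODELS_NAMES:
        raise ParameterError(f"unknown method {method!r}; use one of {CORRECTION_METHODS}")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method=_STATSMODELS_NAMES[method])[1]


@dataclass(frozen=True)
class ScreenResult:
    """Univariate screening with every correction applied."""

    feature_names: tuple[str, ...]
    raw_p: np.ndarray
    adjusted: dict  # method -> adjusted p-values
    alpha: float

    def significant(self, method: str | None = None) -> np.ndarray:
        p = self.raw_p if method is None else self.adjusted[method]
        return p < self.alpha

    def any_significant(self, method: str | None = None) -> bool:
        return bool(self.significant(method).any())


def screen(table: FeatureTable, alpha: float = 0.05,
           methods=CORRECTION_METHODS) -> ScreenResult:
    """Univariate MWW screen plus all requested corrections."""
    raw = univariate_screen(table)
    adjusted = {m: adjust_pvalues(raw, m) for m in methods}
    return ScreenResult(
        feature_names=tuple(table.features.columns),
        raw_p=raw,
        adjusted=adjusted,
        alpha=alpha,
    )


def median_heuristic_bandwidth(Z: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pooled sample."""
    d = pdist(Z)
    med = float(np.median(d))
    if med == 0:
        # degenerate cloud (many identical points); fall back to any positive scale
        nz = d[d > 0]
        med = float(np.median(nz)) if len(nz) else 1.0
    return med


def mmd2_unbiased(K: np.ndarray, is_a: np.ndarray) -> float:
    """Unbiased squared-MMD U-statistic from a precomputed kernel matrix.

    MMD^2_u = sum_{i != j in A} K_ij / (m(m-1)) + sum_{i != j in B} K_ij /
    (n(n-1)) - 2 * sum_{i in A, j in B} K_ij / (mn).  May be negative when
    the groups coincide.
    """
    m = int(is_a.sum())
    n = len(is_a) - m
    if m < 2 or n < 2:
        raise ParameterError("each group needs at least 2 rows")
    Ka = K[np.ix_(is_a, is_a)]
    Kb = K[np.ix_(~is_a, ~is_a)]
    Kab = K[np.ix_(is_a, ~is_a)]
    term_a = (Ka.sum() - np.trace(Ka)) / (m * (m - 1))
    term_b = (Kb.sum() - np.trace(Kb)) / (n * (n - 1))
    return float(term_a + term_b - 2.0 * Kab.sum() / (m * n))


def mmd_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    bandwidth: float | None = None,
) -> tuple[float, float]:
    """Gaussian-kernel unbiased squared-MMD permutation test.

    k(x, y) = exp(-||x - y||^2 / (2 h^2)) with h the pooled median pairwise
    distance unless ``bandwidth`` is given.  The p-value is the add-one
    estimator (b + 1) / (B + 1) over label permutations, with the statistic
    recomputed on the fixed kernel matrix per permutation.
    Returns (statistic, p_value).
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ParameterError("groups must have the same dimensionality")
    if len(A) < 2 or len(B) < 2:
        raise ParameterError("each group needs at least 2 rows")
    Z = np.vstack([A, B])
    h = bandwidth if bandwidth is not None else median_heuristic_bandwidth(Z)
    if h <= 0:
        raise ParameterError("bandwidth must be positive")
    K = np.exp(-squareform(pdist(Z, "sqeuclidean")) / (2.0 * h * h))
    m = len(A)
    is_a = np.zeros(len(Z), dtype=bool)
    is_a[:m] = True
    observed = mmd2_unbiased(K, is_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(Z))
        mask = np.zeros(len(Z), dtype=bool)
        mask[perm[:m]] = True
        if mmd2_unbiased(K, mask) >= observed:
            exceed += 1
    pvalue = (exceed + 1) / (n_permutations + 1)
    return observed, float(pvalue)


def mmd_test_table(table: FeatureTable, n_permutations: int = 1000,
                   seed: int = 0, bandwidth: float | None = None):
    """MMD test between the positive and negative rows of a feature table."""
    X = table.X
    pos = table.labels > 0
    return mmd_test(X[pos], X[~pos], n_permutations=n_permutations,
                    seed=seed, bandwidth=bandwidth)
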