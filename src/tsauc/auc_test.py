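"""The ts-AUC two-sample test.

Given an n x D feature table with binary labels, the test asks whether the two
groups are distinguishable at all: H0: AUC* = 1/2 against H1: AUC* > 1/2,
where AUC* is the maximal out-of-bag AUC attainable by a random-subspace
forest over a small grid of (LS, M) hyperparameters.  Each subject is scored
by the average positive-class posterior over the trees that left it out of
their bootstrap (OOB), so no data splitting is needed; the grid search picks
(LS*, M*) maximizing the Mann-Whitney AUC of those OOB scores, a fresh forest
is refit at (LS*, M*), and the final one-sided Mann-Whitney-Wilcoxon p-value
is computed on its OOB posteriors over the whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import FeatureTable, ParameterError
from .forest import (
    DegenerateLabelsError,
    ForestModel,
    Hyperparameters,
    fit_forest,
    oob_posteriors,
)

LEAF_SIZE_GRID = tuple(range(8, 20))
MAX_FEATURES_PER_TREE = 8
# largest N_F * N_NF for which the exact MWW null distribution is used
EXACT_PAIR_LIMIT = 400


def mww_u(P: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney U: pairs (pos, neg) with P_pos > P_neg, ties counting 1/2.

    Computed via midranks; equivalent to the brute-force double loop.
    """
    P = np.asarray(P, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels > 0
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes must be present among scores")
    ranks = stats.rankdata(P)
    return float(ranks[pos].sum() - n_pos * (n_pos + 1) / 2)


def auc_from_u(U: float, n_pos: int, n_neg: int) -> float:
    """Empirical AUC from the Mann-Whitney identity AUC = U / (N_F * N_NF)."""
    if n_pos < 1 or n_neg < 1:
        raise DegenerateLabelsError("need at least one subject per class")
    return float(U) / (n_pos * n_neg)


def mww_pvalue(P: np.ndarray, labels: np.ndarray, method: str = "auto") -> float:
    """One-sided MWW p-value for 'positives are ranked higher'.

    ``method``: 'exact' (permutation-exact null, tie-free), 'asymptotic'
    (normal approximation with tie and continuity correction), or 'auto'
    (exact when N_F * N_NF <= 400 and there are no ties).
    """
    P = np.asarray(P, dtype=np.float64)
    labels = np.asarray(labels)
    pos = P[labels > 0]
    neg = P[labels <= 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError("both classes must be present among scores")
    if method == "auto":
        ties = len(np.unique(P)) < len(P)
        method = "exact" if (len(pos) * len(neg) <= EXACT_PAIR_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="greater", method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class TsAucResult:
    """Outcome of the ts-AUC test."""

    auc_star: float
    best_hp: Hyperparameters
    oob_posteriors: np.ndarray  # P*, NaN for never-OOB subjects
    u_statistic: float
    p_value: float
    n_pos: int
    n_neg: int
    grid_trace: tuple  # (LS, M, AUC) triples in exploration order
    model: ForestModel | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _grid_auc(table: FeatureTable, hp: Hyperparameters) -> tuple[float, np.ndarray]:
    model = fit_forest(table, hp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        P = oob_posteriors(model, table)
    scored = ~np.isnan(P)
    y = table.labels[scored]
    U = mww_u(P[scored], y)
    return auc_from_u(U, int((y > 0).sum()), int((y < 0).sum())), P


def search_hyperparameters(
    table: FeatureTable,
    n_trees: int = 200,
    seed: int = 0,
    leaf_sizes=LEAF_SIZE_GRID,
    max_features: int | None = None,
):
    """Exhaustive grid search for the OOB-AUC-maximizing (LS, M).

    Ties are broken toward the simpler model: larger LS first, then smaller M.
    Returns (LS*, M*, AUC*, grid_trace).
    """
    if max_features is None:
        max_features = min(MAX_FEATURES_PER_TREE, table.n_dims)
    max_features = min(max_features, table.n_dims)
    feasible = [ls for ls in leaf_sizes if table.n >= 2 * ls]
    if not feasible:
        raise ParameterError(
            f"n={table.n} is too small for any leaf size in {list(leaf_sizes)}"
        )
    ss = np.random.SeedSequence(seed)
    grid = [(ls, m) for ls in feasible for m in range(1, max_features + 1)]
    seeds = ss.generate_state(len(grid), dtype=np.uint32)
    trace = []
    for (ls, m), s in zip(grid, seeds):
        hp = Hyperparameters(leaf_size=ls, n_features=m, n_trees=n_trees, seed=int(s))
        auc, _ = _grid_auc(table, hp)
        trace.append((ls, m, auc))
    # argmax; ties -> larger LS, then smaller M
    best = max(trace, key=lambda r: (r[2], r[0], -r[1]))
    return best[0], best[1], best[2], tuple(trace)


def ts_auc_test(
    table: FeatureTable,
    n_trees: int = 200,
    seed: int = 0,
    leaf_sizes=LEAF_SIZE_GRID,
    max_features: int | None = None,
    keep_model: bool = False,
    p_method: str = "auto",
) -> TsAucResult:
    """Run the full ts-AUC test on a labeled feature table.

    Grid search selects (LS*, M*); a fresh forest (new seed) is refit at the
    optimum and its OOB posteriors P* feed the final one-sided MWW test.
    """
    if table.n_pos == 0 or table.n_neg == 0:
        raise DegenerateLabelsError("both classes must be present")
    ss = np.random.SeedSequence(seed)
    search_seed, refit_seed = (int(s) for s in ss.generate_state(2, dtype=np.uint32))
    ls_star, m_star, auc_star, trace = search_hyperparameters(
        table, n_trees=n_trees, seed=search_seed,
        leaf_sizes=leaf_sizes, max_features=max_features,
    )
    hp_star = Hyperparameters(
        leaf_size=ls_star, n_features=m_star, n_trees=n_trees, seed=refit_seed
    )
    model = fit_forest(table, hp_star)
    P = oob_posteriors(model, table)
    scored = ~np.isnan(P)
    y = table.labels[scored]
    U = mww_u(P[scored], y)
    p = mww_pvalue(P[scored], y, method=p_method)
    return TsAucResult(
        auc_star=auc_star,
        best_hp=hp_star,
        oob_posteriors=P,
        u_statistic=U,
        p_value=p,
        n_pos=int((y > 0).sum()),
        n_neg=int((y < 0).sum()),
        grid_trace=trace,
        model=model if keep_model else None,
    )
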