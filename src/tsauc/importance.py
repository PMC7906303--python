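"""Out-of-bag permutation feature importance and nested model selection.

For each feature j, only the trees whose random feature subset contains j
qualify.  For each qualifying tree the OOB misclassification error is
computed before and after permuting column j among that tree's OOB subjects;
d_j is the mean error increase over qualifying trees, sigma_j its standard
deviation, and the importance score is I_j = d_j / sigma_j.

Interpretation then uses a nested-model rule: refit forests on the top-k
features (k = 1..D, descending importance), record the mean and sd of the OOB
AUC over R fresh runs, and select the smallest k whose mean OOB AUC reaches
the maximum mean minus the sd at the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .auc_test import auc_from_u, mww_u
from .datasets import FeatureTable, ParameterError
from .forest import ForestModel, Hyperparameters, fit_forest, oob_posteriors

# importance assigned when sigma_j = 0 but d_j != 0 (tiny forests only)
SIGMA_ZERO_SENTINEL = 1e6


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature permutation importance and (optionally) nested selection."""

    feature_names: tuple[str, ...]
    d: np.ndarray  # mean OOB error increase per feature (NaN if unused)
    sigma: np.ndarray  # sd of the increase across qualifying trees
    importance: np.ndarray  # I_j = d_j / sigma_j (NaN if feature unused)
    n_trees_used: np.ndarray  # qualifying-tree count per feature
    ranking: tuple[int, ...]  # defined features, descending I_j
    nested_auc_mean: np.ndarray | None = None  # (D,) mean OOB AUC of top-k model
    nested_auc_sd: np.ndarray | None = None
    selected_k: int | None = None
    selected_features: tuple[int, ...] | None = None

    @property
    def ranked_names(self) -> tuple[str, ...]:
        return tuple(self.feature_names[j] for j in self.ranking)


def permutation_importance(
    model: ForestModel,
    table: FeatureTable,
    seed: int = 0,
    n_repeats: int = 1,
) -> ImportanceReport:
    """OOB permutation importance restricted to each feature's own trees.

    One permutation per (feature, tree) by default (the classical scheme);
    ``n_repeats`` averages several.  Features that no tree used are flagged
    NaN and excluded from the ranking; ranking ties break by feature index.
    """
    if model.n_subjects != table.n or model.n_dims != table.n_dims:
        raise ParameterError("model was fitted on a different table shape")
    seeds = np.random.SeedSequence(seed).generate_state(
        model.n_trees, dtype=np.uint32
    ).astype(np.int64)
    base_err, perm_err = _kernels.permutation_error_kernel(
        model.feat,
        model.thr,
        model.left,
        model.right,
        model.val,
        model.tree_feature_sets,
        model.inbag_counts,
        table.X,
        table.y01,
        seeds,
        n_repeats,
    )
    D = table.n_dims
    d = np.full(D, np.nan)
    sigma = np.full(D, np.nan)
    I = np.full(D, np.nan)
    used = np.zeros(D, np.int64)
    fsets = model.tree_feature_sets
    for j in range(D):
        rows, cols = np.nonzero(fsets == j)
        ok = ~np.isnan(base_err[rows])
        rows, cols = rows[ok], cols[ok]
        if len(rows) == 0:
            continue
        inc = perm_err[rows, cols] - base_err[rows]
        used[j] = len(inc)
        d[j] = inc.mean()
        sigma[j] = inc.std(ddof=1) if len(inc) > 1 else 0.0
        if sigma[j] > 0:
            I[j] = d[j] / sigma[j]
        elif d[j] == 0:
            I[j] = 0.0
        else:
            I[j] = np.sign(d[j]) * SIGMA_ZERO_SENTINEL
            warnings.warn(
                f"feature {j}: zero sd of error change with nonzero mean; "
                "sentinel importance assigned"
            )
    defined = np.flatnonzero(~np.isnan(I))
    # descending importance; ties broken by feature index (ascending)
    ranking = tuple(defined[np.lexsort((defined, -I[defined]))])
    return ImportanceReport(
        feature_names=tuple(table.features.columns),
        d=d,
        sigma=sigma,
        importance=I,
        n_trees_used=used,
        ranking=ranking,
    )


def nested_model_selection(
    table: FeatureTable,
    ranking,
    hp_star: Hyperparameters,
    runs: int = 20,
    seed: int = 0,
) -> ImportanceReport | tuple:
    """Nested top-k OOB-AUC curve and the smallest acceptable model.

    For k = 1..len(ranking), fit ``runs`` fresh forests on the top-k features
    with LS = LS* and M = min(M*, k); the selected k is the smallest whose
    mean OOB AUC is >= (max mean) - (sd at the argmax).
    Returns (nested_auc_mean, nested_auc_sd, selected_k, selected_features).
    """
    ranking = tuple(int(j) for j in ranking)
    if len(ranking) == 0:
        raise ParameterError("ranking must be non-empty")
    if runs < 2:
        raise ParameterError("runs must be >= 2 (sd of the runs is needed)")
    ss = np.random.SeedSequence(seed)
    D = len(ranking)
    means = np.empty(D)
    sds = np.empty(D)
    seeds = ss.generate_state(D * runs, dtype=np.uint32).reshape(D, runs)
    names = table.features.columns
    for ki in range(D):
        cols = [names[j] for j in ranking[: ki + 1]]
        sub = FeatureTable(table.features[cols].copy(), table.labels)
        aucs = np.empty(runs)
        for r in range(runs):
            hp = Hyperparameters(
                leaf_size=hp_star.leaf_size,
                n_features=min(hp_star.n_features, ki + 1),
                n_trees=hp_star.n_trees,
                seed=int(seeds[ki, r]),
            )
            model = fit_forest(sub, hp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                P = oob_posteriors(model, sub)
            scored = ~np.isnan(P)
            y = sub.labels[scored]
            U = mww_u(P[scored], y)
            aucs[r] = auc_from_u(U, int((y > 0).sum()), int((y < 0).sum()))
        means[ki] = aucs.mean()
        sds[ki] = aucs.std(ddof=1)
    k_max = int(np.argmax(means))
    threshold = means[k_max] - sds[k_max]
    selected_k = int(np.flatnonzero(means >= threshold)[0]) + 1
    return means, sds, selected_k, tuple(ranking[:selected_k])


def importance_analysis(
    model: ForestModel,
    table: FeatureTable,
    hp_star: Hyperparameters | None = None,
    runs: int = 20,
    seed: int = 0,
    n_repeats: int = 1,
) -> ImportanceReport:
    """Scores + nested selection in one report."""
    ss = np.random.SeedSequence(seed)
    s_imp, s_nested = (int(s) for s in ss.generate_state(2, dtype=np.uint32))
    report = permutation_importance(model, table, seed=s_imp, n_repeats=n_repeats)
    means, sds, k, feats = nested_model_selection(
        table, report.ranking, hp_star or model.hp, runs=runs, seed=s_nested
    )
    return ImportanceReport(
        feature_names=report.feature_names,
        d=report.d,
        sigma=report.sigma,
        importance=report.importance,
        n_trees_used=report.n_trees_used,
        ranking=report.ranking,
        nested_auc_mean=means,
        nested_auc_sd=sds,
        selected_k=k,
        selected_features=feats,
    )
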