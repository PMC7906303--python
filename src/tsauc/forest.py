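"""Random-subspace forest with out-of-bag bookkeeping.

Each of the T trees draws (a) a bootstrap resample of the n subjects (so the
expected out-of-bag fraction is (1 - 1/n)^n, about 36.8%) and (b) its own
uniform subset of M features; the tree then grows greedy Gini splits over
those M features only, down to a minimum leaf size LS.  Recording the per-tree
in-bag/OOB index sets and feature subsets is what makes OOB posterior scoring
and OOB-restricted permutation importance well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .datasets import FeatureTable, ParameterError


class DegenerateLabelsError(ValueError):
    """Both classes are required but only one is present."""


@dataclass(frozen=True)
class Hyperparameters:
    """Forest hyperparameters: LS (min leaf size), M (features per tree), T."""

    leaf_size: int
    n_features: int
    n_trees: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 7 < self.leaf_size < 20:
            raise ParameterError("leaf_size must satisfy 7 < LS < 20")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")


@dataclass(frozen=True)
class ForestModel:
    """A fitted ensemble plus its resampling bookkeeping."""

    hp: Hyperparameters
    n_subjects: int
    n_dims: int
    # packed tree arrays, one row per tree
    feat: np.ndarray
    thr: np.ndarray
    left: np.ndarray
    right: np.ndarray
    val: np.ndarray
    tree_feature_sets: np.ndarray  # (T, M) global feature indices
    inbag_counts: np.ndarray  # (T, n) bootstrap multiplicities

    @property
    def n_trees(self) -> int:
        return self.feat.shape[0]

    @property
    def inbag_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(c > 0) for c in self.inbag_counts]

    @property
    def oob_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(c == 0) for c in self.inbag_counts]

    def oob_fractions(self) -> np.ndarray:
        """Per-tree fraction of subjects left out of the bootstrap."""
        return (self.inbag_counts == 0).mean(axis=1)

    def predict_tree(self, t: int, X: np.ndarray) -> np.ndarray:
        """Leaf positive-class fraction of tree t for rows of X."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _kernels.predict_tree_kernel(
            self.feat[t],
            self.thr[t],
            self.left[t],
            self.right[t],
            self.val[t],
            self.tree_feature_sets[t],
            X,
        )


def _tree_seeds(seed: int, n_trees: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_trees, dtype=np.uint32).astype(np.int64)


def fit_forest(
    table: FeatureTable, hp: Hyperparameters, bootstrap: bool = True
) -> ForestModel:
    """Fit a random-subspace forest on a labeled feature table.

    ``bootstrap=False`` switches to the without-replacement variant that holds
    out an exact 36.8% OOB subsample per tree (sensitivity analysis only).
    """
    if table.n_pos == 0 or table.n_neg == 0:
        raise DegenerateLabelsError("both classes must be present")
    if hp.n_features > table.n_dims:
        raise ParameterError("n_features exceeds the table dimensionality")
    if table.n < 2 * hp.leaf_size:
        raise ParameterError("n must be at least 2 * leaf_size")
    X = table.X
    y = table.y01
    seeds = _tree_seeds(hp.seed, hp.n_trees)
    feat, thr, left, right, val, fsets, inbag = _kernels.fit_forest_kernel(
        X, y, hp.leaf_size, hp.n_features, hp.n_trees, seeds, bootstrap
    )
    return ForestModel(
        hp=hp,
        n_subjects=table.n,
        n_dims=table.n_dims,
        feat=feat,
        thr=thr,
        left=left,
        right=right,
        val=val,
        tree_feature_sets=fsets,
        inbag_counts=inbag,
    )


def oob_posteriors(model: ForestModel, table: FeatureTable) -> np.ndarray:
    """Per-subject averaged OOB posterior probability of the positive class.

    Subject i's score is the mean, over the trees whose bootstrap left i out,
    of the positive-class fraction of the in-bag subjects in the leaf i lands
    in.  Subjects that are OOB in zero trees (probability ~(1-e^-1)^T,
    negligible at T=200) get NaN and a warning; callers must drop them.
    """
    if model.n_subjects != table.n or model.n_dims != table.n_dims:
        raise ParameterError("model was fitted on a different table shape")
    ssum, cnt = _kernels.oob_posterior_kernel(
        model.feat,
        model.thr,
        model.left,
        model.right,
        model.val,
        model.tree_feature_sets,
        model.inbag_counts,
        table.X,
    )
    P = np.full(table.n, np.nan)
    scored = cnt > 0
    P[scored] = ssum[scored] / cnt[scored]
    if not scored.all():
        warnings.warn(
            f"{int((~scored).sum())} subject(s) were OOB in zero trees; "
            "their posterior is NaN and they are excluded from the test"
        )
    return P
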