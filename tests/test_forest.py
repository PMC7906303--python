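"""Random-subspace forest: bootstrap bookkeeping, split optimality, OOB scores."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tsauc import (
    DegenerateLabelsError,
    FeatureTable,
    GaussianDesign,
    Hyperparameters,
    ParameterError,
    fit_forest,
    oob_posteriors,
    simulate_gaussian_groups,
)
from tsauc._kernels import _build_tree, predict_tree_kernel


def route_leaf(feat, thr, left, right, row):
    node = 0
    while feat[node] >= 0:
        node = left[node] if row[feat[node]] <= thr[node] else right[node]
    return node


def brute_force_root_split(X, y, min_leaf):
    """Best (gain, feature, threshold) over all valid midpoint splits."""
    n, M = X.shape
    p = y.mean()
    parent = 2 * p * (1 - p)
    best = (0.0, -1, 0.0)
    for j in range(M):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            t = (a + b) / 2
            mask = X[:, j] <= t
            nl, nr = mask.sum(), (~mask).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            pl, pr = y[mask].mean(), y[~mask].mean()
            child = (nl * 2 * pl * (1 - pl) + nr * 2 * pr * (1 - pr)) / n
            gain = parent - child
            if gain > best[0]:
                best = (gain, j, t)
    return best


class TestTreeBuilder:
    @pytest.mark.parametrize("seed", range(5))
    def test_root_split_is_gini_optimal(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 3))
        y = (rng.random(40) < 0.5).astype(np.int64)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        min_leaf = 8
        cap = 2 * 40 + 1
        feat = np.full(cap, -1, np.int32)
        thr = np.zeros(cap)
        left = np.zeros(cap, np.int32)
        right = np.zeros(cap, np.int32)
        val = np.zeros(cap)
        _build_tree(X, y, min_leaf, feat, thr, left, right, val)
        gain, j, t = brute_force_root_split(X, y, min_leaf)
        if gain <= 1e-12:
            assert feat[0] == -1
        else:
            # root achieves the brute-force optimal impurity reduction
            mask = X[:, feat[0]] <= thr[0]
            pl, pr = y[mask].mean(), y[~mask].mean()
            nl, nr = mask.sum(), (~mask).sum()
            child = (nl * 2 * pl * (1 - pl) + nr * 2 * pr * (1 - pr)) / 40
            parent = 2 * y.mean() * (1 - y.mean())
            assert parent - child == pytest.approx(gain, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_sklearn_on_fixtures(self, seed):
        """Cross-check against an independent CART implementation; small
        disagreement from equal-gain tie-breaking is allowed."""
        sktree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((120, 4))
        y = ((X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(120)) > 0)
        y = y.astype(np.int64)
        cap = 2 * 120 + 1
        feat = np.full(cap, -1, np.int32)
        thr = np.zeros(cap)
        left = np.zeros(cap, np.int32)
        right = np.zeros(cap, np.int32)
        val = np.zeros(cap)
        _build_tree(X, y, 10, feat, thr, left, right, val)
        mine = predict_tree_kernel(feat, thr, left, right, val,
                                   np.arange(4), X)
        sk = sktree.DecisionTreeClassifier(min_samples_leaf=10).fit(X, y)
        theirs = sk.predict_proba(X)[:, 1]
        assert np.mean(np.isclose(mine, theirs)) > 0.8

    def test_min_leaf_size_respected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3))
        y = (X[:, 0] > 0).astype(np.int64)
        min_leaf = 12
        cap = 201
        feat = np.full(cap, -1, np.int32)
        thr = np.zeros(cap)
        left = np.zeros(cap, np.int32)
        right = np.zeros(cap, np.int32)
        val = np.zeros(cap)
        _build_tree(X, y, min_leaf, feat, thr, left, right, val)
        leaves = {}
        for row in X:
            leaf = route_leaf(feat, thr, left, right, row)
            leaves[leaf] = leaves.get(leaf, 0) + 1
        assert all(c >= min_leaf for c in leaves.values())


class TestForestFit:
    def test_mean_oob_fraction_near_e_inverse(self):
        table = simulate_gaussian_groups(
            GaussianDesign(100, 0.5, 5, 0.0, 0.2, seed=1)
        )
        model = fit_forest(table, Hyperparameters(10, 3, 200, seed=1))
        assert 0.33 < model.oob_fractions().mean() < 0.41

    def test_inbag_oob_partition(self):
        table = simulate_gaussian_groups(
            GaussianDesign(50, 0.5, 4, 0.0, 0.25, seed=2)
        )
        model = fit_forest(table, Hyperparameters(8, 2, 20, seed=2))
        for inbag, oob in zip(model.inbag_sets, model.oob_sets):
            merged = np.sort(np.concatenate([inbag, oob]))
            assert np.array_equal(merged, np.arange(50))
        assert np.all(model.inbag_counts.sum(axis=1) == 50)

    def test_full_feature_subset_when_m_equals_d(self):
        table = simulate_gaussian_groups(
            GaussianDesign(60, 0.5, 4, 0.0, 0.25, seed=3)
        )
        model = fit_forest(table, Hyperparameters(9, 4, 10, seed=3))
        assert np.all(model.tree_feature_sets == np.arange(4))

    def test_deterministic_under_fixed_seed(self):
        table = simulate_gaussian_groups(
            GaussianDesign(60, 0.5, 6, 0.5, 0.5, seed=4)
        )
        hp = Hyperparameters(10, 3, 30, seed=5)
        m1, m2 = fit_forest(table, hp), fit_forest(table, hp)
        assert np.array_equal(m1.feat, m2.feat)
        assert np.array_equal(m1.thr, m2.thr)
        assert np.array_equal(m1.inbag_counts, m2.inbag_counts)
        m3 = fit_forest(table, Hyperparameters(10, 3, 30, seed=6))
        assert not np.array_equal(m1.inbag_counts, m3.inbag_counts)

    def test_exact_subsample_mode(self):
        table = simulate_gaussian_groups(
            GaussianDesign(100, 0.5, 5, 0.0, 0.2, seed=5)
        )
        model = fit_forest(table, Hyperparameters(10, 3, 50, seed=7),
                           bootstrap=False)
        fracs = model.oob_fractions()
        assert np.allclose(fracs, fracs[0])
        assert fracs[0] == pytest.approx(np.exp(-1), abs=0.01)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(30.0)})
        with pytest.raises(DegenerateLabelsError):
            fit_forest(FeatureTable(X, np.ones(30, int)),
                       Hyperparameters(8, 1, 5, seed=0))

    def test_infeasible_sizes_rejected(self):
        table = simulate_gaussian_groups(
            GaussianDesign(20, 0.5, 3, 0.0, 1 / 3, seed=6)
        )
        with pytest.raises(ParameterError):
            fit_forest(table, Hyperparameters(11, 1, 5, seed=0))
        with pytest.raises(ParameterError):
            fit_forest(table, Hyperparameters(8, 5, 5, seed=0))
        with pytest.raises(ParameterError):
            Hyperparameters(7, 1, 5, seed=0)
        with pytest.raises(ParameterError):
            Hyperparameters(20, 1, 5, seed=0)


class TestOobPosteriors:
    def test_matches_per_tree_reference(self):
        """P_i equals the average, over trees with i OOB, of the leaf
        positive fraction -- recomputed tree by tree in Python."""
        table = simulate_gaussian_groups(
            GaussianDesign(60, 0.5, 5, 0.8, 0.4, seed=8)
        )
        model = fit_forest(table, Hyperparameters(8, 3, 25, seed=9))
        P = oob_posteriors(model, table)
        X = table.X
        for i in range(table.n):
            vals = [model.predict_tree(t, X[i : i + 1])[0]
                    for t in range(model.n_trees)
                    if model.inbag_counts[t, i] == 0]
            if vals:
                assert P[i] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(P[i])

    def test_leaf_value_is_inbag_positive_fraction(self):
        """Each leaf's posterior equals the multiplicity-weighted positive
        fraction of the in-bag subjects that reach it."""
        table = simulate_gaussian_groups(
            GaussianDesign(50, 0.4, 4, 1.0, 0.5, seed=10)
        )
        model = fit_forest(table, Hyperparameters(8, 2, 10, seed=11))
        X, y = table.X, table.y01
        for t in range(model.n_trees):
            counts = {}
            for i in range(table.n):
                c = model.inbag_counts[t, i]
                if c == 0:
                    continue
                leaf = route_leaf(model.feat[t], model.thr[t], model.left[t],
                                  model.right[t],
                                  X[i, model.tree_feature_sets[t]])
                tot, pos = counts.get(leaf, (0, 0))
                counts[leaf] = (tot + c, pos + c * y[i])
            for leaf, (tot, pos) in counts.items():
                assert model.val[t][leaf] == pytest.approx(pos / tot)

    def test_never_oob_subjects_flagged(self):
        table = simulate_gaussian_groups(
            GaussianDesign(40, 0.5, 3, 0.0, 1 / 3, seed=12)
        )
        model = fit_forest(table, Hyperparameters(8, 2, 1, seed=13))
        with pytest.warns(UserWarning, match="OOB in zero trees"):
            P = oob_posteriors(model, table)
        assert np.array_equal(np.isnan(P), model.inbag_counts[0] > 0)

    def test_pure_leaves_for_separable_table(self, separable_table):
        model = fit_forest(separable_table, Hyperparameters(8, 4, 50, seed=14))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            P = oob_posteriors(model, separable_table)
        scored = ~np.isnan(P)
        assert np.isin(P[scored], [0.0, 1.0]).all()

    def test_shape_mismatch_rejected(self, separable_table, null_table):
        model = fit_forest(separable_table, Hyperparameters(8, 2, 5, seed=0))
        with pytest.raises(ParameterError):
            oob_posteriors(model, null_table)
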