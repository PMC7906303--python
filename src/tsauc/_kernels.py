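"""Numba kernels for the random-subspace forest.

These are low-level routines; the public surface is in :mod:`tsauc.forest`.
Each tree is grown on a bootstrap resample restricted to its own feature
subset, with greedy Gini splits and a minimum-leaf-size stopping rule.
Trees are stored as flat parallel arrays (``feature < 0`` marks a leaf,
``value`` is the in-bag positive-class fraction of the leaf).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# impurity reductions below this are treated as zero (no split)
_MIN_GINI_GAIN = 1e-12


@njit(cache=True)
def _build_tree(Xt, yt, min_leaf, feat, thr, left, right, val):
    """Grow one tree in place; Xt is the in-bag matrix in subset-column space.

    Returns the number of nodes written.
    """
    m_all, M = Xt.shape
    idx = np.arange(m_all)
    stack = np.empty((2 * m_all + 1, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = m_all
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        node = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        m = e - s
        npos = 0
        for i in range(s, e):
            npos += yt[idx[i]]
        val[node] = npos / m
        feat[node] = -1
        if m < 2 * min_leaf or npos == 0 or npos == m:
            continue
        p = npos / m
        parent_gini = 2.0 * p * (1.0 - p)
        best_red = _MIN_GINI_GAIN
        best_j = -1
        best_t = 0.0
        for j in range(M):
            v = np.empty(m, np.float64)
            for i in range(m):
                v[i] = Xt[idx[s + i], j]
            order = np.argsort(v)
            cp = 0
            for k in range(m - 1):
                cp += yt[idx[s + order[k]]]
                nl = k + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                if v[order[k]] == v[order[k + 1]]:
                    continue
                pl = cp / nl
                pr = (npos - cp) / nr
                child = (nl * 2.0 * pl * (1.0 - pl) + nr * 2.0 * pr * (1.0 - pr)) / m
                red = parent_gini - child
                if red > best_red:
                    best_red = red
                    best_j = j
                    best_t = 0.5 * (v[order[k]] + v[order[k + 1]])
        if best_j < 0:
            continue
        tmp = np.empty(m, np.int64)
        a = 0
        b = m - 1
        for i in range(s, e):
            if Xt[idx[i], best_j] <= best_t:
                tmp[a] = idx[i]
                a += 1
            else:
                tmp[b] = idx[i]
                b -= 1
        for i in range(m):
            idx[s + i] = tmp[i]
        mid = s + a
        feat[node] = best_j
        thr[node] = best_t
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack[top, 0] = n_nodes
        stack[top, 1] = s
        stack[top, 2] = mid
        top += 1
        stack[top, 0] = n_nodes + 1
        stack[top, 1] = mid
        stack[top, 2] = e
        top += 1
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def fit_forest_kernel(X, y, min_leaf, M, T, seeds, bootstrap):
    """Fit T trees; returns packed tree arrays, feature subsets, in-bag counts."""
    n, D = X.shape
    cap = 2 * n + 1
    feat = np.full((T, cap), -1, np.int32)
    thr = np.zeros((T, cap), np.float64)
    left = np.zeros((T, cap), np.int32)
    right = np.zeros((T, cap), np.int32)
    val = np.zeros((T, cap), np.float64)
    fsets = np.empty((T, M), np.int64)
    inbag = np.zeros((T, n), np.int64)
    for t in range(T):
        np.random.seed(seeds[t])
        # feature subset: partial Fisher-Yates, then sorted for stable order
        perm = np.arange(D)
        for i in range(M):
            j = i + np.random.randint(0, D - i)
            tmpv = perm[i]
            perm[i] = perm[j]
            perm[j] = tmpv
        fs = np.sort(perm[:M])
        for c in range(M):
            fsets[t, c] = fs[c]
        if bootstrap:
            for _ in range(n):
                inbag[t, np.random.randint(0, n)] += 1
        else:
            # without-replacement subsample holding out the e^-1 OOB fraction
            k = int(round(n * (1.0 - np.exp(-1.0))))
            perm2 = np.arange(n)
            for i in range(k):
                j = i + np.random.randint(0, n - i)
                tmpv = perm2[i]
                perm2[i] = perm2[j]
                perm2[j] = tmpv
            for i in range(k):
                inbag[t, perm2[i]] += 1
        m = 0
        for i in range(n):
            m += inbag[t, i]
        Xt = np.empty((m, M), np.float64)
        yt = np.empty(m, np.int64)
        pos = 0
        for i in range(n):
            for _ in range(inbag[t, i]):
                for c in range(M):
                    Xt[pos, c] = X[i, fs[c]]
                yt[pos] = y[i]
                pos += 1
        _build_tree(Xt, yt, min_leaf, feat[t], thr[t], left[t], right[t], val[t])
    return feat, thr, left, right, val, fsets, inbag


@njit(cache=True)
def predict_tree_kernel(feat, thr, left, right, val, fset, X):
    """Leaf positive-class fraction for each row of X (full-column space)."""
    n = X.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while feat[node] >= 0:
            if X[i, fset[feat[node]]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = val[node]
    return out


@njit(cache=True)
def oob_posterior_kernel(feat, thr, left, right, val, fsets, inbag, X):
    """Sum of leaf fractions and tree counts over each subject's OOB trees."""
    T = feat.shape[0]
    n = X.shape[0]
    ssum = np.zeros(n, np.float64)
    cnt = np.zeros(n, np.int64)
    for t in range(T):
        for i in range(n):
            if inbag[t, i] == 0:
                node = 0
                while feat[t, node] >= 0:
                    if X[i, fsets[t, feat[t, node]]] <= thr[t, node]:
                        node = left[t, node]
                    else:
                        node = right[t, node]
                ssum[i] += val[t, node]
                cnt[i] += 1
    return ssum, cnt


@njit(cache=True)
def permutation_error_kernel(
    feat, thr, left, right, val, fsets, inbag, X, y, seeds, n_repeats
):
    """Per-tree OOB 0/1 error, before and after permuting each subset feature.

    Leaf fractions strictly above 0.5 classify positive.  Permutations shuffle
    the feature's values among that tree's OOB subjects only.  Returns
    (base_err[T], perm_err[T, M]); perm_err is averaged over n_repeats.
    """
    T, M = fsets.shape
    n = X.shape[0]
    base_err = np.full(T, np.nan)
    perm_err = np.full((T, M), np.nan)
    for t in range(T):
        np.random.seed(seeds[t])
        n_oob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                n_oob += 1
        if n_oob == 0:
            continue
        oob = np.empty(n_oob, np.int64)
        pos = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob[pos] = i
                pos += 1
        errs = 0
        for q in range(n_oob):
            i = oob[q]
            node = 0
            while feat[t, node] >= 0:
                if X[i, fsets[t, feat[t, node]]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            pred = 1 if val[t, node] > 0.5 else 0
            if pred != y[i]:
                errs += 1
        base_err[t] = errs / n_oob
        for c in range(M):
            tot = 0.0
            for _ in range(n_repeats):
                # Fisher-Yates shuffle of the OOB column values
                col = np.empty(n_oob, np.float64)
                for q in range(n_oob):
                    col[q] = X[oob[q], fsets[t, c]]
                for q in range(n_oob - 1, 0, -1):
                    r = np.random.randint(0, q + 1)
                    tmpv = col[q]
                    col[q] = col[r]
                    col[r] = tmpv
                errs = 0
                for q in range(n_oob):
                    i = oob[q]
                    node = 0
                    while feat[t, node] >= 0:
                        f = feat[t, node]
                        xv = col[q] if f == c else X[i, fsets[t, f]]
                        if xv <= thr[t, node]:
                            node = left[t, node]
                        else:
                            node = right[t, node]
                    pred = 1 if val[t, node] > 0.5 else 0
                    if pred != y[i]:
                        errs += 1
                tot += errs / n_oob
            perm_err[t, c] = tot / n_repeats
    return base_err, perm_err
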