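"""Benchmark orchestration: power/size grids and population-reduction curves.

Each experiment cell derives its RNG stream from (base seed, cell index,
repeat index) via `numpy.random.SeedSequence` spawn keys, so results are
bit-reproducible and safe to parallelize without changing numbers.  Reports
carry the config hash and base seed needed for exact replay.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .auc_test import ts_auc_test
from .baselines import CORRECTION_METHODS, mmd_test_table, screen
from .datasets import FeatureTable, GaussianDesign, ParameterError, simulate_gaussian_groups

logger = logging.getLogger(__name__)

REDUCTION_FRACTIONS = tuple(np.round(np.arange(0.95, 0.34, -0.10), 2))


@dataclass(frozen=True)
class PowerConfig:
    """Grid of Gaussian two-group designs and the tests to run on each cell."""

    n_totals: tuple = (200,)
    pos_fractions: tuple = (0.5,)
    n_dims_list: tuple = (30,)
    deltas: tuple = (0.0, 0.3, 0.6, 0.9)
    informative_fraction: float = 1 / 3
    tests: tuple = ("ts_auc", "mmd", "screen_hommel")
    runs: int = 20
    alpha: float = 0.05
    n_trees: int = 200
    mmd_permutations: int = 1000
    base_seed: int = 0

    def cells(self):
        i = 0
        for n in self.n_totals:
            for pf in self.pos_fractions:
                for d in self.n_dims_list:
                    for delta in self.deltas:
                        yield i, dict(n_total=n, pos_fraction=pf,
                                      n_dims=d, delta=delta)
                        i += 1

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RejectionCurve:
    """Per-cell rejection fractions with run-level p-values retained."""

    results: pd.DataFrame  # one row per (cell, test): rejection_fraction
    pvalues: pd.DataFrame  # one row per (cell, test, run): p_value
    config_hash: str
    base_seed: int

    def to_json(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "base_seed": self.base_seed,
            "results": self.results.to_dict(orient="records"),
            "pvalues": self.pvalues.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _run_test(name: str, table: FeatureTable, cfg, seed: int) -> float:
    """Return the p-value proxy of one test on one table.

    For corrected screens the proxy is the minimum adjusted p-value, so
    `p < alpha` means "any feature survives the correction".
    """
    if name == "ts_auc":
        return ts_auc_test(table, n_trees=cfg.n_trees, seed=seed).p_value
    if name == "mmd":
        return mmd_test_table(
            table, n_permutations=cfg.mmd_permutations, seed=seed
        )[1]
    if name.startswith("screen"):
        _, _, method = name.partition("_")
        res = screen(table, alpha=cfg.alpha)
        p = res.raw_p if method in ("", "raw") else res.adjusted[method]
        return float(p.min())
    raise ParameterError(f"unknown test {name!r}")


def power_experiment(cfg: PowerConfig) -> RejectionCurve:
    """Rejection fraction of each test over the simulated design grid."""
    if cfg.runs < 1:
        raise ParameterError("runs must be >= 1")
    rows, prows = [], []
    for cell_idx, cell in cfg.cells():
        for test in cfg.tests:
            n_reject = 0
            skipped = False
            for rep in range(cfg.runs):
                ss = np.random.SeedSequence(cfg.base_seed,
                                            spawn_key=(cell_idx, rep))
                table_seed, test_seed = (int(s) for s in
                                         ss.generate_state(2, dtype=np.uint32))
                design = GaussianDesign(
                    n_total=cell["n_total"],
                    pos_fraction=cell["pos_fraction"],
                    n_dims=cell["n_dims"],
                    delta=cell["delta"],
                    informative_fraction=cfg.informative_fraction,
                    seed=table_seed,
                )
                table = simulate_gaussian_groups(design)
                try:
                    p = _run_test(test, table, cfg, test_seed)
                except ParameterError as exc:
                    logger.warning("cell %d (%s) infeasible, skipped: %s",
                                   cell_idx, test, exc)
                    skipped = True
                    break
                prows.append({**cell, "test": test, "run": rep, "p_value": p})
                n_reject += p < cfg.alpha
            if not skipped:
                rows.append({**cell, "test": test,
                             "rejection_fraction": n_reject / cfg.runs})
    return RejectionCurve(
        results=pd.DataFrame(rows),
        pvalues=pd.DataFrame(prows),
        config_hash=cfg.hash(),
        base_seed=cfg.base_seed,
    )


def _subsample(table: FeatureTable, scheme: str, fraction: float,
               rng: np.random.Generator) -> FeatureTable:
    pos_idx = np.flatnonzero(table.labels > 0)
    neg_idx = np.flatnonzero(table.labels < 0)
    if scheme == "uniform":
        for _ in range(100):
            keep = rng.choice(table.n, size=int(round(fraction * table.n)),
                              replace=False)
            sub = table.subset(np.sort(keep))
            if sub.n_pos > 0 and sub.n_neg > 0:
                return sub
            logger.warning("subsample lost a class; redrawing")
        raise ParameterError("could not draw a two-class subsample")
    if scheme == "negatives_only":
        k = int(round(fraction * len(neg_idx)))
        if k < 1:
            raise ParameterError("reduction removes all negatives")
        keep_neg = rng.choice(neg_idx, size=k, replace=False)
        keep = np.sort(np.concatenate([pos_idx, keep_neg]))
        return table.subset(keep)
    raise ParameterError(f"unknown scheme {scheme!r}")


def reduction_experiment(
    table: FeatureTable,
    scheme: str = "uniform",
    fractions=REDUCTION_FRACTIONS,
    repeats: int = 12,
    seed: int = 0,
    tests: tuple = ("ts_auc",),
    alpha: float = 0.05,
    n_trees: int = 200,
    mmd_permutations: int = 1000,
) -> RejectionCurve:
    """Rejection fraction of each test as the cohort is progressively reduced.

    ``scheme='uniform'`` subsamples the whole cohort; ``'negatives_only'``
    keeps every positive subject and subsamples negatives (class balancing).
    """
    cfg = PowerConfig(tests=tuple(tests), runs=repeats, alpha=alpha,
                      n_trees=n_trees, mmd_permutations=mmd_permutations,
                      base_seed=seed)
    rows, prows = [], []
    for cell_idx, fraction in enumerate(fractions):
        for test in tests:
            n_reject = 0
            n_done = 0
            for rep in range(repeats):
                ss = np.random.SeedSequence(seed, spawn_key=(cell_idx, rep))
                sub_seed, test_seed = (int(s) for s in
                                       ss.generate_state(2, dtype=np.uint32))
                sub = _subsample(table, scheme, fraction,
                                 np.random.default_rng(sub_seed))
                try:
                    p = _run_test(test, sub, cfg, test_seed)
                except ParameterError as exc:
                    logger.warning("fraction %.2f (%s) infeasible: %s",
                                   fraction, test, exc)
                    continue
                prows.append({"fraction": fraction, "test": test, "run": rep,
                              "p_value": p, "n": sub.n, "n_pos": sub.n_pos})
                n_reject += p < alpha
                n_done += 1
            if n_done:
                rows.append({"fraction": fraction, "test": test,
                             "rejection_fraction": n_reject / n_done})
    meta = json.dumps({"scheme": scheme, "fractions": list(map(float, fractions)),
                       "repeats": repeats, "tests": list(tests),
                       "alpha": alpha, "n_trees": n_trees}, sort_keys=True)
    return RejectionCurve(
        results=pd.DataFrame(rows),
        pvalues=pd.DataFrame(prows),
        config_hash=hashlib.sha256(meta.encode()).hexdigest()[:16],
        base_seed=seed,
    )
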