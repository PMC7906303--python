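"""Synthetic inputs: Gaussian two-group feature tables and CoP trajectories.

The Gaussian designs mix two independent groups in D dimensions: a fraction of
"informative" dimensions carries a mean shift ``delta`` in the positive group,
the rest are identical N(0, 1) noise in both groups.  Informative dimensions
are always the LAST columns, and their names are recorded on the table so
downstream importance analyses can refer to them.  The CoP generator is a
discretized Ornstein-Uhlenbeck walk with exact transitions, giving closed-form
stationary variance for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """An invalid design or simulation parameter."""


@dataclass(frozen=True)
class FeatureTable:
    """An n x D matrix of named real features with binary group labels.

    Labels are +1 (positive class, e.g. fallers) and -1 (negative class).
    ``informative`` names the columns that carry a designed group difference
    (empty for real data).
    """

    features: pd.DataFrame
    labels: np.ndarray
    informative: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.features) != len(self.labels):
            raise ParameterError("features and labels must have equal length")
        lab = np.asarray(self.labels)
        if not np.isin(lab, [-1, 1]).all():
            raise ParameterError("labels must be -1 or +1")
        object.__setattr__(self, "labels", lab.astype(np.int64))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_dims(self) -> int:
        return self.features.shape[1]

    @property
    def X(self) -> np.ndarray:
        return np.ascontiguousarray(self.features.to_numpy(dtype=np.float64))

    @property
    def y01(self) -> np.ndarray:
        """Labels recoded to {0, 1}."""
        return (self.labels > 0).astype(np.int64)

    @property
    def n_pos(self) -> int:
        return int((self.labels > 0).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels < 0).sum())

    def to_csv(self, path_or_buf) -> None:
        df = self.features.copy()
        df["label"] = self.labels
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, label_col: str = "label") -> "FeatureTable":
        df = pd.read_csv(path_or_buf)
        if label_col not in df.columns:
            raise ParameterError(f"missing label column {label_col!r}")
        labels = df[label_col].to_numpy()
        return cls(df.drop(columns=[label_col]), labels)

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.features.iloc[rows].reset_index(drop=True),
            self.labels[rows],
            self.informative,
        )


@dataclass(frozen=True)
class GaussianDesign:
    """Two-group Gaussian simulation design.

    ``informative_fraction`` of the ``n_dims`` dimensions (the last ones in
    index order) have positive-group mean ``delta``; all other dimensions, and
    every dimension of the negative group, are N(0, 1).
    """

    n_total: int
    pos_fraction: float
    n_dims: int
    delta: float
    informative_fraction: float
    seed: int

    def __post_init__(self):
        if not 0.0 < self.pos_fraction < 1.0:
            raise ParameterError("pos_fraction must lie strictly in (0, 1)")
        if self.n_dims < 1:
            raise ParameterError("n_dims must be >= 1")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ParameterError("informative_fraction must lie in [0, 1]")
        if self.n_total < 2:
            raise ParameterError("n_total must be >= 2")

    @property
    def n_pos(self) -> int:
        return int(round(self.pos_fraction * self.n_total))

    @property
    def n_informative(self) -> int:
        return int(round(self.informative_fraction * self.n_dims))


def _feature_names(n_dims: int) -> list[str]:
    width = max(2, len(str(n_dims)))
    return [f"f{i:0{width}d}" for i in range(1, n_dims + 1)]


def simulate_gaussian_groups(design: GaussianDesign) -> FeatureTable:
    """Draw a labeled two-group Gaussian table for the given design.

    Reproducible: a fixed design (including its seed) yields a bit-identical
    table.
    """
    rng = np.random.default_rng(design.seed)
    n, D = design.n_total, design.n_dims
    n_pos = design.n_pos
    if n_pos == 0 or n_pos == n:
        raise ParameterError("design yields a single class; adjust pos_fraction")
    X = rng.standard_normal((n, D))
    labels = np.full(n, -1, np.int64)
    labels[:n_pos] = 1
    k = design.n_informative
    if k > 0:
        X[:n_pos, D - k :] += design.delta
    names = _feature_names(D)
    table = FeatureTable(
        pd.DataFrame(X, columns=names), labels, tuple(names[D - k :]) if k else ()
    )
    return table


def simulate_importance_design(n_total: int, seed: int) -> FeatureTable:
    """Two balanced Gaussian groups in 30 dimensions for importance studies.

    Columns f01-f22 are N(0, 1) in both groups; columns f23-f30 are N(0.9, 1)
    in the positive group only.  Columns are mutually independent.
    """
    if n_total < 4:
        raise ParameterError("n_total must be >= 4")
    design = GaussianDesign(
        n_total=n_total,
        pos_fraction=0.5,
        n_dims=30,
        delta=0.9,
        informative_fraction=8 / 30,
        seed=seed,
    )
    return simulate_gaussian_groups(design)


@dataclass(frozen=True)
class CopSimParams:
    """Ornstein-Uhlenbeck CoP sway parameters.

    ``sd_ml``/``sd_ap`` are the diffusion scales (cm/sqrt(s)) of the ML (x) and
    AP (y) axes; the stationary displacement variance per axis is
    sd^2 / (2 * reversion_rate).  Defaults match a 25 s recording at 25 Hz.
    """

    duration: float = 25.0
    fs: float = 25.0
    reversion_rate: float = 1.0
    sd_ml: float = 0.5
    sd_ap: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.fs <= 0:
            raise ParameterError("duration and fs must be positive")
        if self.sd_ml <= 0 or self.sd_ap <= 0:
            raise ParameterError("sd_ml and sd_ap must be positive")
        if self.reversion_rate <= 0:
            raise ParameterError("reversion_rate must be positive")


def simulate_cop_trajectory(params: CopSimParams, group_effect: float = 1.0):
    """Simulate a statokinesigram as an exact-discretized OU walk.

    ``group_effect`` scales the AP diffusion (a crude faller profile: larger
    AP variance and velocity).  Both axes start from their stationary law, so
    Var[x_k] = sd_ml^2/(2*theta) and Var[y_k] = (group_effect*sd_ap)^2/(2*theta)
    at every sample.
    """
    from .posturography import Statokinesigram

    if group_effect <= 0:
        raise ParameterError("group_effect must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    if n < 2:
        raise ParameterError("duration * fs must give at least 2 samples")
    dt = 1.0 / params.fs
    theta = params.reversion_rate
    decay = np.exp(-theta * dt)
    t = np.arange(n) * dt
    xy = np.empty((n, 2))
    for axis, sd in enumerate((params.sd_ml, params.sd_ap * group_effect)):
        stat_sd = sd / np.sqrt(2.0 * theta)
        step_sd = stat_sd * np.sqrt(1.0 - decay**2)
        z = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = stat_sd * z[0]
        for k in range(1, n):
            x[k] = decay * x[k - 1] + step_sd * z[k]
        xy[:, axis] = x
    return Statokinesigram(t=t, x=xy[:, 0], y=xy[:, 1], fs=params.fs)
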