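"""Center-of-pressure (CoP) sway features from statokinesigrams.

A statokinesigram is the 2D trajectory of the body's center of pressure during
quiet standing, sampled uniformly (nominally 25 Hz for 25 s): x is the
medio-lateral (ML) displacement, y the antero-posterior (AP) displacement,
both in cm.  Seventeen standard posturographic features are extracted:

========  =======  =====================================================
Feature   Unit     Definition used here
========  =======  =====================================================
RangeX/Y  cm       max - min displacement per axis
MaxX/Y    cm       maximum displacement (right / front)
MinX/Y    cm       minimum displacement (left / back)
VarianceX/Y cm^2   sample variance (ddof=1) per axis
VelocityX/Y cm/s   mean absolute first difference x fs
AccelerationX/Y cm/s^2  mean absolute second difference x fs^2
F95X/Y    Hz       spectral edge: smallest periodogram frequency below
                   which 95% of the (DC-removed) power lies
DistC     cm       mean Euclidean distance to the trajectory centroid
EllArea   cm^2     area of the 95% covariance confidence ellipse,
                   pi * chi2_{2,0.95} * sqrt(det(cov))
AngularDeviation deg  mean absolute turning angle between consecutive
                   nonzero displacement steps
========  =======  =====================================================

Velocity, acceleration, F95, DistC and AngularDeviation have no universally
fixed formula in the posturography literature; the dialects above are the
package's declared choices (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .datasets import FeatureTable, ParameterError

FEATURE_NAMES = (
    "RangeX",
    "MaxX",
    "MinX",
    "VarianceX",
    "VelocityX",
    "AccelerationX",
    "F95X",
    "RangeY",
    "MaxY",
    "MinY",
    "VarianceY",
    "VelocityY",
    "AccelerationY",
    "F95Y",
    "DistC",
    "EllArea",
    "AngularDeviation",
)

# chi-square quantile with 2 d.f. at 0.95; scales the covariance ellipse
_CHI2_2DF_95 = float(stats.chi2.ppf(0.95, df=2))


class InsufficientDataError(ValueError):
    """Too few samples to compute the requested feature."""


@dataclass(frozen=True)
class Statokinesigram:
    """Uniformly sampled 2D CoP trajectory (t in s, x/y in cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=np.float64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (len(t) == len(x) == len(y)):
            raise ParameterError("t, x, y must have equal length")
        if len(t) < 2:
            raise ParameterError("a trajectory needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ParameterError("time stamps must be strictly increasing")
        nominal = 1.0 / self.fs
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ParameterError(
                "sampling must be uniform within 1% of 1/fs (resampling is out "
                "of scope; resample upstream)"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf, fs: float | None = None) -> "Statokinesigram":
        df = pd.read_csv(path_or_buf)
        for col in ("t_s", "x_cm", "y_cm"):
            if col not in df.columns:
                raise ParameterError(f"missing column {col!r}")
        t = df["t_s"].to_numpy(dtype=np.float64)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t=t, x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy(), fs=fs)


def mean_speed(coord: np.ndarray, fs: float) -> float:
    """Mean absolute instantaneous velocity (cm/s): mean |first diff| * fs."""
    coord = np.asarray(coord, dtype=np.float64)
    if len(coord) < 2:
        raise InsufficientDataError("velocity needs >= 2 samples")
    return float(np.mean(np.abs(np.diff(coord))) * fs)


def mean_accel(coord: np.ndarray, fs: float) -> float:
    """Mean absolute instantaneous acceleration (cm/s^2): mean |2nd diff| * fs^2."""
    coord = np.asarray(coord, dtype=np.float64)
    if len(coord) < 3:
        raise InsufficientDataError("acceleration needs >= 3 samples")
    return float(np.mean(np.abs(np.diff(coord, n=2))) * fs**2)


def spectral_edge_f95(coord: np.ndarray, fs: float, fraction: float = 0.95) -> float:
    """Spectral edge frequency (Hz).

    Smallest one-sided raw-periodogram frequency f such that the cumulative
    power over (0, f] reaches ``fraction`` of the total power over (0, fs/2].
    The mean is removed first and the DC bin is excluded from "energy"; an
    (effectively) constant series returns 0 by convention.
    """
    coord = np.asarray(coord, dtype=np.float64)
    if len(coord) < 16:
        raise InsufficientDataError("spectral edge needs >= 16 samples")
    freqs, pxx = signal.periodogram(coord, fs=fs, detrend="constant", window="boxcar")
    freqs, pxx = freqs[1:], pxx[1:]  # drop DC
    total = pxx.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(pxx)
    k = int(np.searchsorted(cum, fraction * total))
    return float(freqs[min(k, len(freqs) - 1)])


def mean_dist_center(s: Statokinesigram) -> float:
    """Mean Euclidean distance from each sample to the trajectory centroid (cm)."""
    dx = s.x - s.x.mean()
    dy = s.y - s.y.mean()
    return float(np.mean(np.hypot(dx, dy)))


def confidence_ellipse_area(s: Statokinesigram, coverage: float = 0.95) -> float:
    """Area (cm^2) of the covariance-based confidence ellipse.

    pi * c * sqrt(det(Sigma)) with Sigma the 2x2 sample covariance and c the
    chi-square(2 d.f.) quantile at ``coverage``.  Degenerate (collinear)
    clouds return 0 with a warning.
    """
    if len(s) < 3:
        raise InsufficientDataError("ellipse area needs >= 3 samples")
    cov = np.cov(np.vstack([s.x, s.y]), ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0:
        warnings.warn("degenerate (collinear) trajectory; ellipse area set to 0")
        return 0.0
    c = float(stats.chi2.ppf(coverage, df=2))
    return float(np.pi * c * np.sqrt(det))


def angular_deviation(s: Statokinesigram) -> float:
    """Mean absolute turning angle (degrees) between consecutive steps.

    Zero-length steps are skipped; a trajectory with no pair of consecutive
    nonzero steps returns 0 with a warning.
    """
    if len(s) < 3:
        raise InsufficientDataError("angular deviation needs >= 3 samples")
    steps = np.column_stack([np.diff(s.x), np.diff(s.y)])
    norms = np.hypot(steps[:, 0], steps[:, 1])
    keep = norms > 0
    steps, norms = steps[keep], norms[keep]
    if len(steps) < 2:
        warnings.warn("no consecutive nonzero steps; angular deviation set to 0")
        return 0.0
    u = steps / norms[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    return float(np.degrees(np.mean(np.arccos(cosang))))


def extract_features(s: Statokinesigram) -> dict[str, float]:
    """All 17 posturographic features of a statokinesigram, by name."""
    if len(s) < 3:
        raise InsufficientDataError("feature extraction needs >= 3 samples")
    out: dict[str, float] = {}
    for axis, coord in (("X", s.x), ("Y", s.y)):
        out[f"Max{axis}"] = float(coord.max())
        out[f"Min{axis}"] = float(coord.min())
        out[f"Range{axis}"] = out[f"Max{axis}"] - out[f"Min{axis}"]
        out[f"Variance{axis}"] = float(np.var(coord, ddof=1))
        out[f"Velocity{axis}"] = mean_speed(coord, s.fs)
        out[f"Acceleration{axis}"] = mean_accel(coord, s.fs)
        out[f"F95{axis}"] = (
            spectral_edge_f95(coord, s.fs) if len(s) >= 16 else 0.0
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["DistC"] = mean_dist_center(s)
        out["EllArea"] = confidence_ellipse_area(s)
        out["AngularDeviation"] = angular_deviation(s)
    return {name: out[name] for name in FEATURE_NAMES}


def features_table(
    trajectories, labels=None, fs: float | None = None
) -> FeatureTable | pd.DataFrame:
    """Extract features from many trajectories into a table.

    With ``labels`` given, returns a :class:`FeatureTable`; otherwise a plain
    DataFrame of feature rows.
    """
    rows = [extract_features(s) for s in trajectories]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is None:
        return df
    return FeatureTable(df, np.asarray(labels))
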