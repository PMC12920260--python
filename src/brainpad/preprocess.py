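"""Input normalization: trilinear resampling, intensity clipping/z-scoring,
and age scaling.

The chain mirrors a standard brain-age preparation: volumes are
isotropically resampled to the model grid by trilinear interpolation,
intensities are clipped at the 1st/99th percentile of each volume and
z-scored within volume (mean 0, SD 1), and the age target is standardized
with a scaler fitted on the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin


def resample_volume(data: np.ndarray, target_edge: int) -> np.ndarray:
    """Trilinearly resample a cubic volume to ``target_edge`` per axis.

    Sampling is corner-aligned: output coordinates span the full input
    extent, so an identity target reproduces the input exactly.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(f"expected a cubic 3D volume, got shape {data.shape}")
    if target_edge < 2:
        raise ValueError("target_edge must be >= 2")
    n = data.shape[0]
    if target_edge == n:
        return data.copy()
    coords = np.linspace(0.0, n - 1.0, target_edge)
    grid = np.meshgrid(coords, coords, coords, indexing="ij")
    out = ndimage.map_coordinates(data, np.stack(grid), order=1, mode="nearest")
    return out.astype(np.float32)


def normalize_intensity(data: np.ndarray, p_lo: float = 1.0,
                        p_hi: float = 99.0) -> np.ndarray:
    """Clip at the (p_lo, p_hi) percentiles of the volume, then z-score.

    Percentiles use linear interpolation between order statistics. The
    z-step uses the post-clip mean and population SD, so the output has
    mean 0 and SD 1 up to floating-point error.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    lo, hi = np.percentile(data, [p_lo, p_hi])
    clipped = np.clip(data, lo, hi)
    sd = clipped.std()
    if sd == 0:
        raise ValueError("zero variance: volume is constant after clipping")
    return ((clipped - clipped.mean()) / sd).astype(np.float32)


@dataclass
class AgeScaler:
    """Standardizes ages with the training partition's mean and SD.

    The SD is the population convention (divide by n). Fit once on the
    training subjects; validation, test and patient ages reuse it.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"AgeScaler sd must be > 0, got {self.sd}")

    @classmethod
    def fit(cls, train_ages) -> "AgeScaler":
        ages = np.asarray(train_ages, dtype=float)
        if np.unique(ages).size < 2:
            raise ValueError("need >= 2 distinct training ages to fit the scaler")
        return cls(mean=float(ages.mean()), sd=float(ages.std(ddof=0)))

    def apply(self, ages):
        return (np.asarray(ages, dtype=float) - self.mean) / self.sd

    def invert(self, scaled):
        return np.asarray(scaled, dtype=float) * self.sd + self.mean


def fit_age_scaler(train_ages) -> AgeScaler:
    """Convenience wrapper for :meth:`AgeScaler.fit`."""
    return AgeScaler.fit(train_ages)


class VolumePreprocessor(TransformerMixin, BaseEstimator):
    """Stateless per-volume preprocessing transformer.

    Resamples each cubic volume to ``target_edge`` and applies
    clip-then-z intensity normalization. Accepts a stack of volumes
    (n, d, d, d) or flattened rows (n, d**3).
    """

    def __init__(self, target_edge: int = 32, p_lo: float = 1.0,
                 p_hi: float = 99.0):
        self.target_edge = target_edge
        self.p_lo = p_lo
        self.p_hi = p_hi

    def fit(self, X, y=None):
        X = self._as_stack(X)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X):
        X = self._as_stack(X)
        out = np.empty((X.shape[0],) + (self.target_edge,) * 3, dtype=np.float32)
        for i, vol in enumerate(X):
            out[i] = normalize_intensity(
                resample_volume(vol, self.target_edge), self.p_lo, self.p_hi)
        return out

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4:
            return X
        if X.ndim == 2:
            edge = round(X.shape[1] ** (1.0 / 3.0))
            if edge ** 3 != X.shape[1]:
                raise ValueError(
                    f"cannot reshape {X.shape[1]} features into a cube")
            return X.reshape(X.shape[0], edge, edge, edge)
        raise ValueError(f"expected (n, d, d, d) or (n, d^3), got {X.shape}")
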