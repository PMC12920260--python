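"""The covariate-conditioned 3D CNN age regressor, scikit-learn style.

:class:`BrainAgeRegressor` is a fit/predict estimator trained on healthy
controls only (normative modelling). Training follows the standard
protocol for this architecture: Huber loss on standardized ages, AdamW,
gradient-norm clipping at 1.0, on-the-fly affine augmentation of training
volumes, validation-loss early stopping and plateau learning-rate
reduction. The reference (full-scale) architecture is five blocks with
channels 16-256 and a 512-unit head at a 128-voxel grid; the estimator
defaults are a reduced desk-scale configuration (three blocks, 8-32
channels, 32-voxel grid) that trains in minutes on one CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import AdamW, BrainAgeCNN, clip_grad_norm, huber_loss
from .preprocess import AgeScaler


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters. Defaults are the full-scale reference."""

    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    kernel: int = 3
    head_units: int = 512
    head_dropout: float = 0.1
    film: bool = True
    sex_batchnorm: bool = True

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.channels[1:], self.channels[:-1])):
            raise ValueError("channels must be strictly increasing")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol. Defaults are the full-scale reference values."""

    lr: float = 1e-4
    weight_decay: float = 1e-5
    huber_delta: float = 1.0
    grad_clip_norm: float = 1.0
    batch_size: int = 32
    max_epochs: int = 150
    early_stop_patience: int = 15
    lr_reduce_patience: int = 5
    lr_reduce_factor: float = 0.5
    augment: bool = True
    rot_deg: float = 5.0
    translate_frac: float = 0.05
    scale_range: float = 0.1
    flip_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr", "weight_decay", "huber_delta", "grad_clip_norm",
                     "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patiences must be >= 1")


@dataclass
class Partition:
    """Train/validation/test split over healthy controls; patients held out."""

    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)
    held_out: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        hc = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if hc[i] & hc[j]:
                    raise ValueError(f"overlapping partition lists: {hc[i] & hc[j]}")
        held = set().union(*self.held_out.values()) if self.held_out else set()
        leak = held & (hc[0] | hc[1] | hc[2])
        if leak:
            raise ValueError(f"held-out subjects present in HC partition: {leak}")


def split_cohort(hc_ids, fractions=(0.6, 0.2, 0.2), seed: int = 0,
                 strata=None, held_out: dict | None = None) -> Partition:
    """Randomly partition healthy-control ids into train/val/test.

    Sizes are floor-allocated for validation and test with the remainder
    going to training (155 ids at the default fractions give 93/31/31).
    If ``strata`` (a label per id, e.g. sex x age-decile) is given, the
    shuffle interleaves strata so each set is approximately balanced;
    exact set sizes are preserved either way.
    """
    hc_ids = list(hc_ids)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(hc_ids)
    if n < 5:
        raise ValueError(f"need at least 5 HC subjects, got {n}")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    if strata is None:
        order = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("strata must have one label per id")
        # shuffle within strata, then deal round-robin across strata so
        # contiguous slices of the order are stratum-balanced
        buckets = []
        for s in pd.unique(strata):
            idx = np.where(strata == s)[0]
            buckets.append(list(rng.permutation(idx)))
        order = []
        while any(buckets):
            for b in buckets:
                if b:
                    order.append(b.pop())
        order = np.asarray(order)
    ids = [hc_ids[i] for i in order]
    return Partition(train=ids[:n_train], val=ids[n_train:n_train + n_val],
                     test=ids[n_train + n_val:], held_out=dict(held_out or {}))


def augment_volume(vol: np.ndarray, rng: np.random.Generator,
                   rot_deg: float = 5.0, translate_frac: float = 0.05,
                   scale_range: float = 0.1, flip_p: float = 0.5) -> np.ndarray:
    """Random small 3D affine (rotation, translation, scale) plus
    left-right flip with probability ``flip_p``. Shape-preserving;
    out-of-source voxels are zero-filled."""
    vol = np.asarray(vol, dtype=np.float32)
    if vol.ndim != 3 or len(set(vol.shape)) != 1:
        raise ValueError(f"expected a cubic volume, got {vol.shape}")
    n = vol.shape[0]
    angles = rng.uniform(-rot_deg, rot_deg, size=3) * np.pi / 180.0
    scale = rng.uniform(1.0 - scale_range, 1.0 + scale_range)
    shift = rng.uniform(-translate_frac, translate_frac, size=3) * n
    flip = rng.random() < flip_p

    def rot(axis, a):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        m[i, i] = c
        m[i, j] = -s
        m[j, i] = s
        m[j, j] = c
        return m

    mat = rot(0, angles[0]) @ rot(1, angles[1]) @ rot(2, angles[2]) / scale
    center = (n - 1) / 2.0
    offset = center - mat @ (center + shift)
    out = ndimage.affine_transform(vol, mat, offset=offset, order=1, cval=0.0,
                                   output=np.float32)
    if flip:
        out = out[::-1].copy()  # left-right (first-axis) mirror
    return out


class _CategoryEncoder:
    """Maps categorical covariate labels to stable integer indices."""

    def __init__(self, levels):
        self.levels = list(levels)
        self._index = {lv: i for i, lv in enumerate(self.levels)}

    def encode(self, values, name: str) -> np.ndarray:
        values = np.asarray(values)
        out = np.empty(values.shape[0], dtype=int)
        for i, v in enumerate(values):
            if v not in self._index:
                raise ValueError(f"unseen {name} level {v!r}; known: {self.levels}")
            out[i] = self._index[v]
        return out


class BrainAgeRegressor(RegressorMixin, BaseEstimator):
    """3D CNN age regressor with scanner FiLM and sex-stratified batch norm.

    Parameters follow the training protocol of the full-scale reference
    model but default to a reduced configuration sized for CPU use. Pass
    preprocessed volumes (see :class:`~brainpad.preprocess.VolumePreprocessor`)
    as ``X`` with shape (n, d, d, d) or flattened (n, d**3).

    Covariates ``sex`` and ``scanner`` are optional label arrays; omitted
    covariates collapse the corresponding conditioning to a single level.
    """

    def __init__(self, channels=(8, 16, 32), head_units=64, head_dropout=0.1,
                 film=True, sex_batchnorm=True, lr=1e-3, weight_decay=1e-5,
                 huber_delta=1.0, grad_clip_norm=1.0, batch_size=32,
                 max_epochs=60, early_stop_patience=15, lr_reduce_patience=5,
                 lr_reduce_factor=0.5, augment=True, rot_deg=5.0,
                 translate_frac=0.05, scale_range=0.1, flip_p=0.5,
                 val_fraction=0.2, random_state=0):
        self.channels = channels
        self.head_units = head_units
        self.head_dropout = head_dropout
        self.film = film
        self.sex_batchnorm = sex_batchnorm
        self.lr = lr
        self.weight_decay = weight_decay
        self.huber_delta = huber_delta
        self.grad_clip_norm = grad_clip_norm
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.lr_reduce_patience = lr_reduce_patience
        self.lr_reduce_factor = lr_reduce_factor
        self.augment = augment
        self.rot_deg = rot_deg
        self.translate_frac = translate_frac
        self.scale_range = scale_range
        self.flip_p = flip_p
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _as_volumes(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            edge = round(X.shape[1] ** (1.0 / 3.0))
            if edge ** 3 != X.shape[1]:
                raise ValueError(f"cannot reshape {X.shape[1]} features to a cube")
            X = X.reshape(X.shape[0], edge, edge, edge)
        if X.ndim != 4 or len(set(X.shape[1:])) != 1:
            raise ValueError(f"expected (n, d, d, d) volumes, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("volumes contain non-finite values")
        return X

    def _encode(self, sex, scanner, n):
        sex_idx = (self._sex_enc_.encode(sex, "sex")
                   if sex is not None else np.zeros(n, dtype=int))
        sc_idx = (self._scanner_enc_.encode(scanner, "scanner")
                  if scanner is not None else np.zeros(n, dtype=int))
        return sex_idx, sc_idx

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y, sex=None, scanner=None, X_val=None, y_val=None,
            sex_val=None, scanner_val=None):
        X = self._as_volumes(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        grid = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        self._sex_enc_ = _CategoryEncoder(
            pd.unique(np.asarray(sex)) if sex is not None else [0])
        self._scanner_enc_ = _CategoryEncoder(
            pd.unique(np.asarray(scanner)) if scanner is not None else [0])
        sex_idx, sc_idx = self._encode(sex, scanner, X.shape[0])

        if X_val is None:
            # carve an internal validation split off the training data
            n = X.shape[0]
            n_val = max(1, int(np.floor(self.val_fraction * n)))
            perm = rng.permutation(n)
            vi, ti = perm[:n_val], perm[n_val:]
            X_val, y_val = X[vi], y[vi]
            sexv, scv = sex_idx[vi], sc_idx[vi]
            X, y, sex_idx, sc_idx = X[ti], y[ti], sex_idx[ti], sc_idx[ti]
        else:
            X_val = self._as_volumes(X_val)
            y_val = np.asarray(y_val, dtype=float)
            sexv, scv = self._encode(sex_val, scanner_val, X_val.shape[0])

        if X.shape[0] < 2 or X_val.shape[0] < 1:
            raise ValueError("need at least 2 training and 1 validation subjects")

        self.scaler_ = AgeScaler.fit(y)
        y_s = self.scaler_.apply(y)
        yv_s = self.scaler_.apply(y_val)

        net = BrainAgeCNN(
            grid=grid, channels=tuple(self.channels), head_units=self.head_units,
            head_dropout=self.head_dropout, n_sexes=len(self._sex_enc_.levels),
            n_scanners=len(self._scanner_enc_.levels), film=self.film,
            sex_batchnorm=self.sex_batchnorm, rng=rng)
        params = net.params()
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay)

        best_val = np.inf
        best_state = None
        best_epoch = 0
        since_best = 0
        since_lr = 0
        history = []
        n_train = X.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n_train)
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, n_train, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                if self.augment:
                    xb = np.stack([
                        augment_volume(v, rng, self.rot_deg, self.translate_frac,
                                       self.scale_range, self.flip_p)
                        for v in xb])
                pred = net.forward(xb, sex_idx[idx], sc_idx[idx], train=True,
                                   rng=rng)
                loss, dpred = huber_loss(pred, y_s[idx], self.huber_delta)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}")
                opt.zero_grad()
                net.backward(dpred)
                clip_grad_norm(params, self.grad_clip_norm)
                opt.step()
                ep_loss += loss
                n_batches += 1
            # exact population batch-norm statistics at the current weights,
            # so validation (and inference) are stable despite few batches
            if n_train <= 256:
                net.recalibrate_stats(X, sex_idx, sc_idx)
            else:
                sub = rng.choice(n_train, size=256, replace=False)
                net.recalibrate_stats(X[sub], sex_idx[sub], sc_idx[sub])
            val_pred = self._forward_eval(net, X_val, sexv, scv)
            val_loss, _ = huber_loss(val_pred, yv_s, self.huber_delta)
            history.append({"epoch": epoch, "train_loss": ep_loss / n_batches,
                            "val_loss": val_loss, "lr": opt.lr})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = copy.deepcopy(net.state_arrays())
                best_epoch = epoch
                since_best = 0
                since_lr = 0
            else:
                since_best += 1
                since_lr += 1
                if since_lr >= self.lr_reduce_patience:
                    opt.lr *= self.lr_reduce_factor
                    since_lr = 0
                if since_best >= self.early_stop_patience:
                    break
        if best_state is not None:
            net.load_state_arrays(best_state)
        self.model_ = net
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        return self

    def _forward_eval(self, net, X, sex_idx, sc_idx) -> np.ndarray:
        preds = []
        for start in range(0, X.shape[0], self.batch_size):
            sl = slice(start, start + self.batch_size)
            preds.append(net.forward(X[sl], sex_idx[sl], sc_idx[sl], train=False))
        return np.concatenate(preds)

    def predict(self, X, sex=None, scanner=None) -> np.ndarray:
        """Predicted age in years (deterministic: dropout off, running stats)."""
        if not hasattr(self, "model_"):
            raise ValueError("BrainAgeRegressor is not fitted yet")
        X = self._as_volumes(X)
        sex_idx, sc_idx = self._encode(sex, scanner, X.shape[0])
        scaled = self._forward_eval(self.model_, X, sex_idx, sc_idx)
        return self.scaler_.invert(scaled)
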