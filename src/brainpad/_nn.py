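"""Compact CPU neural-network engine for the 3D brain-age regressor.

Implements exactly the layers the architecture needs — 3x3x3 same-padding
convolutions (via im2col), batch normalization with optional per-sex
statistic sets, per-scanner feature-wise linear modulation (FiLM), ReLU,
2x2x2 max pooling, dense layers, dropout — together with analytic
backpropagation, the Huber loss, global gradient-norm clipping, and a
decoupled-weight-decay Adam (AdamW) optimizer. Gradients with respect to
intermediate block activations are exposed for Grad-CAM.

All tensors are float32 numpy arrays with layout (N, C, D, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether AdamW weight decay applies


# ---------------------------------------------------------------------------
# layers


class Conv3d:
    """3x3x3 convolution, stride 1, same (zero) padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        fan_in = c_in * k ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.k = k
        self.W = Param(w, decay=True)
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # (N, C, D, H, W, k, k, k) -> (N, D*H*W, C*k^3); reshape copies
        n, c, d, h, w = x.shape
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, d * h * w, c * k ** 3)
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        cols = self._im2col(x)
        wf = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wf.T + self.b.value
        self._cache = (cols, x.shape)
        return y.transpose(0, 2, 1).reshape(n, -1, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, d, h, w = xshape
        k = self.k
        o = dy.shape[1]
        dyf = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 4, 1)).reshape(n * d * h * w, o)  # (N*P, O)
        cols2 = cols.reshape(n * d * h * w, -1)
        self.W.grad += (cols2.T @ dyf).T.reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        wf = self.W.value.reshape(o, -1)
        dcols = dyf @ wf  # (N*P, C*k^3)
        # one transpose copy so the 27 scatter-adds hit contiguous slabs
        dcols = np.ascontiguousarray(
            dcols.reshape(n, d, h, w, c, k ** 3).transpose(5, 0, 4, 1, 2, 3))
        p = k // 2
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=np.float32)
        t = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i:i + d, j:j + h, l:l + w] += dcols[t]
                    t += 1
        return dxp[:, :, p:-p, p:-p, p:-p]


class BatchNorm3d:
    """Batch normalization with one statistic set per conditioning level.

    With ``n_groups == 1`` this is ordinary batch norm. With more groups
    (here: sex levels), each item is normalized with the batch statistics
    of its own level during training and with that level's running
    statistics at inference; the affine (gamma, beta) is shared.
    """

    def __init__(self, channels: int, n_groups: int = 1, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros((n_groups, channels), dtype=np.float32)
        self.running_var = np.ones((n_groups, channels), dtype=np.float32)
        self.seen = np.zeros(n_groups, dtype=bool)
        self.n_groups = n_groups
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, groups: np.ndarray | None,
                train: bool, exact: bool = False) -> np.ndarray:
        if groups is None or self.n_groups == 1:
            groups = np.zeros(x.shape[0], dtype=int)
        y = np.empty_like(x)
        cache = []
        g_ = self.gamma.value[None, :, None, None, None]
        b_ = self.beta.value[None, :, None, None, None]
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            xs = x[idx]
            if train:
                mean = xs.mean(axis=(0, 2, 3, 4))
                var = xs.var(axis=(0, 2, 3, 4))
                m = self.momentum
                if exact or not self.seen[g]:
                    # exact: replace running stats with this (full-set) pass
                    self.running_mean[g] = mean
                    self.running_var[g] = var
                    self.seen[g] = True
                else:
                    self.running_mean[g] = (1 - m) * self.running_mean[g] + m * mean
                    self.running_var[g] = (1 - m) * self.running_var[g] + m * var
            else:
                if not self.seen[g]:
                    raise ValueError(
                        f"conditioning level {g} was never seen during training")
                mean = self.running_mean[g]
                var = self.running_var[g]
            std = np.sqrt(var + self.eps).astype(np.float32)
            xhat = (xs - mean[None, :, None, None, None]) / std[None, :, None, None, None]
            y[idx] = xhat * g_ + b_
            cache.append((idx, xhat.astype(np.float32), std, train))
        self._cache = cache
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.empty_like(dy)
        gamma = self.gamma.value[None, :, None, None, None]
        for idx, xhat, std, trained_stats in self._cache:
            dys = dy[idx]
            self.gamma.grad += (dys * xhat).sum(axis=(0, 2, 3, 4))
            self.beta.grad += dys.sum(axis=(0, 2, 3, 4))
            dxhat = dys * gamma
            if trained_stats:
                m = xhat.shape[0] * xhat.shape[2] * xhat.shape[3] * xhat.shape[4]
                s1 = dxhat.sum(axis=(0, 2, 3, 4), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
                dx[idx] = (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None, None]
            else:  # inference statistics are constants
                dx[idx] = dxhat / std[None, :, None, None, None]
        return dx


class FiLM:
    """Per-level feature-wise linear modulation: y = gamma[s, c]*x + beta[s, c].

    One (gamma, beta) pair per channel per conditioning level (scanner),
    implemented as a learned lookup table.
    """

    def __init__(self, channels: int, n_levels: int):
        self.gamma = Param(np.ones((n_levels, channels)))
        self.beta = Param(np.zeros((n_levels, channels)))
        self.n_levels = n_levels
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, levels: np.ndarray | None,
                train: bool) -> np.ndarray:
        if levels is None:
            levels = np.zeros(x.shape[0], dtype=int)
        if np.any(levels >= self.n_levels) or np.any(levels < 0):
            bad = sorted(set(levels[(levels >= self.n_levels) | (levels < 0)]))
            raise ValueError(f"unknown conditioning level index(es) {bad}")
        g = self.gamma.value[levels][:, :, None, None, None]
        self._cache = (x, levels)
        return g * x + self.beta.value[levels][:, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, levels = self._cache
        per_item_gx = (dy * x).sum(axis=(2, 3, 4))
        per_item_b = dy.sum(axis=(2, 3, 4))
        np.add.at(self.gamma.grad, levels, per_item_gx)
        np.add.at(self.beta.grad, levels, per_item_b)
        return dy * self.gamma.value[levels][:, :, None, None, None]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool3d:
    """2x2x2 max pooling, stride 2. Requires even spatial extents."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._inshape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._inshape
        flat = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return flat.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Param(w, decay=True)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout:
    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


# ---------------------------------------------------------------------------
# loss, clipping, optimizer


def huber_loss(pred: np.ndarray, target: np.ndarray,
               delta: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean Huber loss and its gradient with respect to ``pred``.

    Quadratic (e^2/2) for |e| <= delta, linear (delta*(|e| - delta/2))
    beyond; averaged over the batch.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    e = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    small = np.abs(e) <= delta
    loss = np.where(small, 0.5 * e ** 2, delta * (np.abs(e) - 0.5 * delta))
    grad = np.where(small, e, delta * np.sign(e)) / e.size
    return float(loss.mean()), grad.astype(np.float32)


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class AdamW:
    """Adam with decoupled weight decay (applied only to flagged params)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 weight_decay: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if p.decay and self.weight_decay > 0:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# the network


class BrainAgeCNN:
    """Covariate-conditioned 3D convolutional age regressor.

    ``channels[i]`` convolution blocks of (conv 3x3x3 -> batch norm with
    per-sex statistics -> scanner FiLM -> ReLU -> 2x2x2 max pool), then a
    dense head (ReLU, dropout) onto a single linear output in scaled-age
    units.
    """

    def __init__(self, grid: int, channels: tuple[int, ...], head_units: int,
                 head_dropout: float, n_sexes: int, n_scanners: int,
                 film: bool, sex_batchnorm: bool, rng: np.random.Generator):
        if any(b >= a for a, b in zip(channels[1:], channels[:-1])):
            raise ValueError(f"channels must be strictly increasing: {channels}")
        if grid % (2 ** len(channels)) != 0:
            raise ValueError(
                f"grid {grid} not divisible by 2^{len(channels)} pooling stages")
        self.grid = grid
        self.channels = tuple(channels)
        self.blocks = []
        c_prev = 1
        for c in channels:
            block = {
                "conv": Conv3d(c_prev, c, rng),
                "bn": BatchNorm3d(c, n_groups=n_sexes if sex_batchnorm else 1),
                "film": FiLM(c, n_scanners) if film else None,
                "relu": ReLU(),
                "pool": MaxPool3d(),
            }
            self.blocks.append(block)
            c_prev = c
        final_edge = grid // (2 ** len(channels))
        self.n_flat = channels[-1] * final_edge ** 3
        self.fc1 = Dense(self.n_flat, head_units, rng)
        self.head_relu = ReLU()
        self.dropout = Dropout(head_dropout)
        self.fc2 = Dense(head_units, 1, rng)
        self.block_activations: list[np.ndarray] = []

    def params(self) -> list[Param]:
        out = []
        for b in self.blocks:
            out += b["conv"].params() + b["bn"].params()
            if b["film"] is not None:
                out += b["film"].params()
        out += self.fc1.params() + self.fc2.params()
        return out

    def forward(self, x: np.ndarray, sex_idx: np.ndarray | None,
                scanner_idx: np.ndarray | None, train: bool,
                rng: np.random.Generator | None = None,
                keep_activations: bool = False) -> np.ndarray:
        """Forward pass; returns predictions in scaled-age units, shape (N,)."""
        h = x[:, None, :, :, :].astype(np.float32)
        self.block_activations = []
        for b in self.blocks:
            h = b["conv"].forward(h, train)
            h = b["bn"].forward(h, sex_idx, train)
            if b["film"] is not None:
                h = b["film"].forward(h, scanner_idx, train)
            h = b["relu"].forward(h, train)
            if keep_activations:
                self.block_activations.append(h)
            h = b["pool"].forward(h, train)
        n = h.shape[0]
        h = h.reshape(n, -1)
        h = self.fc1.forward(h, train)
        h = self.head_relu.forward(h, train)
        h = self.dropout.forward(h, train, rng)
        out = self.fc2.forward(h, train)
        return out[:, 0]

    def recalibrate_stats(self, x: np.ndarray, sex_idx: np.ndarray | None,
                          scanner_idx: np.ndarray | None) -> None:
        """Replace every batch-norm layer's running statistics with the
        exact population statistics of ``x`` (one full-set forward pass
        through the convolutional trunk at the current weights)."""
        h = x[:, None, :, :, :].astype(np.float32)
        for b in self.blocks:
            h = b["conv"].forward(h, False)
            h = b["bn"].forward(h, sex_idx, train=True, exact=True)
            if b["film"] is not None:
                h = b["film"].forward(h, scanner_idx, False)
            h = b["relu"].forward(h, False)
            h = b["pool"].forward(h, False)

    def backward(self, dout: np.ndarray,
                 tap_block: int | None = None) -> np.ndarray | None:
        """Backpropagate d(loss)/d(output); optionally return the gradient
        with respect to block ``tap_block``'s post-ReLU activations
        (0-based) instead of continuing parameter-gradient bookkeeping
        below it."""
        dy = self.fc2.backward(dout[:, None])
        dy = self.dropout.backward(dy)
        dy = self.head_relu.backward(dy)
        dy = self.fc1.backward(dy)
        edge = self.grid // (2 ** len(self.blocks))
        dy = dy.reshape(-1, self.channels[-1], edge, edge, edge)
        for i in range(len(self.blocks) - 1, -1, -1):
            b = self.blocks[i]
            dy = b["pool"].backward(dy)
            if tap_block is not None and i == tap_block:
                return dy  # gradient w.r.t. post-ReLU activations of block i
            dy = b["relu"].backward(dy)
            if b["film"] is not None:
                dy = b["film"].backward(dy)
            dy = b["bn"].backward(dy)
            dy = b["conv"].backward(dy)
        return None

    # -- parameter (de)serialization -------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, b in enumerate(self.blocks):
            state[f"b{i}.conv.W"] = b["conv"].W.value
            state[f"b{i}.conv.b"] = b["conv"].b.value
            state[f"b{i}.bn.gamma"] = b["bn"].gamma.value
            state[f"b{i}.bn.beta"] = b["bn"].beta.value
            state[f"b{i}.bn.rmean"] = b["bn"].running_mean
            state[f"b{i}.bn.rvar"] = b["bn"].running_var
            state[f"b{i}.bn.seen"] = b["bn"].seen
            if b["film"] is not None:
                state[f"b{i}.film.gamma"] = b["film"].gamma.value
                state[f"b{i}.film.beta"] = b["film"].beta.value
        state["fc1.W"] = self.fc1.W.value
        state["fc1.b"] = self.fc1.b.value
        state["fc2.W"] = self.fc2.W.value
        state["fc2.b"] = self.fc2.b.value
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, b in enumerate(self.blocks):
            b["conv"].W.value = np.array(state[f"b{i}.conv.W"], dtype=np.float32)
            b["conv"].b.value = np.array(state[f"b{i}.conv.b"], dtype=np.float32)
            b["bn"].gamma.value = np.array(state[f"b{i}.bn.gamma"], dtype=np.float32)
            b["bn"].beta.value = np.array(state[f"b{i}.bn.beta"], dtype=np.float32)
            b["bn"].running_mean = np.array(state[f"b{i}.bn.rmean"], dtype=np.float32)
            b["bn"].running_var = np.array(state[f"b{i}.bn.rvar"], dtype=np.float32)
            b["bn"].seen = np.array(state[f"b{i}.bn.seen"], dtype=bool)
            if b["film"] is not None:
                b["film"].gamma.value = np.array(state[f"b{i}.film.gamma"],
                                                 dtype=np.float32)
                b["film"].beta.value = np.array(state[f"b{i}.film.beta"],
                                                dtype=np.float32)
        self.fc1.W.value = np.array(state["fc1.W"], dtype=np.float32)
        self.fc1.b.value = np.array(state["fc1.b"], dtype=np.float32)
        self.fc2.W.value = np.array(state["fc2.W"], dtype=np.float32)
        self.fc2.b.value = np.array(state["fc2.b"], dtype=np.float32)
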