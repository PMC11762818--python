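"""Classifier variants for coupling feature tensors: CNN, SECNN, MSCNN, MSSECNN.

All four models share one skeleton operating on H x W x C inputs (NHWC):

    1x1 conv stem (adjusts the band/channel count, spatial dims untouched)
    -> one or three parallel conv branches (3x3 [, 5x5, 7x7], same padding,
       2 output channels each, ReLU, 4x4 max pool stride 4)
    -> channel concatenation
    [-> squeeze-and-excitation channel reweighting]
    -> flatten -> FC 512 (ReLU) -> FC 256 (ReLU) -> FC n_classes -> softmax

The squeeze-and-excitation block implements

    Z_c   = mean_{i,j} X[i, j, c]                      (squeeze)
    S     = sigmoid(W2 @ relu(W1 @ Z))                 (excitation)
    X~    = S_c * X[:, :, c]                           (reweight)

Variant table: cnn = single 3x3 branch; secnn = cnn + SE; mscnn = three
branches; mssecnn = mscnn + SE.  The baselines are strict ablations so the
comparison isolates the multi-scale and SE contributions.

Implemented directly on NumPy in float32 (im2col convolutions, analytic
backprop, Adam in evalcv); inputs are tiny (16 x 16 maps) so this is fast and
fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelHandle",
    "se_squeeze",
    "se_excite",
    "se_reweight",
    "SEParams",
    "build_model",
    "count_params",
    "VARIANTS",
]

VARIANTS = ("cnn", "secnn", "mscnn", "mssecnn")


# ---------------------------------------------------------------------------
# Functional squeeze-and-excitation primitives
# ---------------------------------------------------------------------------

@dataclass
class SEParams:
    """Weights of the excitation bottleneck: W1 maps C -> C/r, W2 maps C/r -> C."""

    W1: np.ndarray  # (C, C//r)
    W2: np.ndarray  # (C//r, C)
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None


def se_squeeze(X: np.ndarray) -> np.ndarray:
    """Global average pooling over the H x W plane: (H, W, C) -> (C,)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("expected H x W x C input")
    return X.mean(axis=(0, 1))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def se_excite(Z: np.ndarray, params: SEParams) -> np.ndarray:
    """Channel weights S = sigmoid(W2 . relu(W1 . Z)); entries in (0, 1)."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] != params.W1.shape[0]:
        raise ValueError("Z length must match W1 input dimension")
    if params.W1.shape[1] != params.W2.shape[0]:
        raise ValueError("W1 output and W2 input dimensions must agree")
    h = Z @ params.W1
    if params.b1 is not None:
        h = h + params.b1
    h = np.maximum(h, 0.0)
    s = h @ params.W2
    if params.b2 is not None:
        s = s + params.b2
    return _sigmoid(s)


def se_reweight(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-channel multiplicative reweighting: X~[i,j,c] = S_c X[i,j,c]."""
    X = np.asarray(X, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if X.shape[-1] != S.shape[0]:
        raise ValueError("channel counts must match")
    return X * S[None, None, :]


# ---------------------------------------------------------------------------
# Layers (batch NHWC tensors, float64)
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2dSame(Layer):
    """k x k convolution, stride 1, same (zero) padding, with bias."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.W = _glorot(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # im2col: one GEMM per layer
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * self.c_in
        )
        self._cols, self._shape = cols, (n, h, w)
        out = cols @ self.W.reshape(-1, self.c_out) + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(n * h * w, self.c_out)
        self.db[...] = dflat.sum(axis=0)
        self.dW[...] = (self._cols.T @ dflat).reshape(self.W.shape)
        dcols = (dflat @ self.W.reshape(-1, self.c_out).T).reshape(
            n, h, w, k, k, self.c_in
        )
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool(Layer):
    """p x p max pooling with stride p (spatial dims must divide by p)."""

    def __init__(self, p: int = 4):
        self.p = p

    def forward(self, x):
        n, h, w, c = x.shape
        p = self.p
        if h % p or w % p:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {p}")
        r = x.reshape(n, h // p, p, w // p, p, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(n, h // p, w // p, p * p, c)
        self._idx = r.argmax(axis=3)
        self._inshape = x.shape
        return np.take_along_axis(r, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._inshape
        p = self.p
        dr = np.zeros((n, h // p, w // p, p * p, c), dtype=DTYPE)
        np.put_along_axis(dr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dr = dr.reshape(n, h // p, w // p, p, p, c).transpose(0, 1, 3, 2, 4, 5)
        return dr.reshape(n, h, w, c)


class ParallelConcat(Layer):
    """Runs branch layer-stacks on one input and concatenates channel outputs."""

    def __init__(self, branches: list[list[Layer]]):
        self.branches = branches

    def params(self):
        return [p for br in self.branches for l in br for p in l.params()]

    def grads(self):
        return [g for br in self.branches for l in br for g in l.grads()]

    def forward(self, x):
        outs = []
        for br in self.branches:
            h = x
            for layer in br:
                h = layer.forward(h)
            outs.append(h)
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, dout):
        douts = np.split(dout, self._splits, axis=-1)
        dx = None
        for br, d in zip(self.branches, douts):
            for layer in reversed(br):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


class SEBlock(Layer):
    """Squeeze / excitation / reweight with a C -> C/r -> C bottleneck (biased)."""

    def __init__(self, c: int, r: int, rng: np.random.Generator):
        if c // r < 1 or c % r:
            raise ValueError(
                f"SE reduction r={r} invalid for C={c}: C/r must be an integer >= 1 "
                "(lower r)"
            )
        cr = c // r
        self.W1 = _glorot(rng, (c, cr), c, cr)
        self.b1 = np.zeros(cr, dtype=DTYPE)
        self.W2 = _glorot(rng, (cr, c), cr, c)
        self.b2 = np.zeros(c, dtype=DTYPE)
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def grads(self):
        return [self.dW1, self.db1, self.dW2, self.db2]

    def forward(self, x):
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))                    # squeeze (N, C)
        a = z @ self.W1 + self.b1
        hmask = a > 0
        hr = a * hmask
        s = _sigmoid(hr @ self.W2 + self.b2)       # excitation (N, C)
        self._cache = (x, z, hmask, hr, s)
        return x * s[:, None, None, :]             # reweight

    def backward(self, dout):
        x, z, hmask, hr, s = self._cache
        n, h, w, c = x.shape
        dx = dout * s[:, None, None, :]
        ds = (dout * x).sum(axis=(1, 2))
        dpre2 = ds * s * (1.0 - s)
        self.dW2[...] = hr.T @ dpre2
        self.db2[...] = dpre2.sum(axis=0)
        dhr = dpre2 @ self.W2.T
        dpre1 = dhr * hmask
        self.dW1[...] = z.T @ dpre1
        self.db1[...] = dpre1.sum(axis=0)
        dz = dpre1 @ self.W1.T
        dx += dz[:, None, None, :] / (h * w)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by the four variants."""

    variant: str = "mssecnn"
    input_hw: tuple[int, int] = (16, 16)
    in_channels: int = 7
    stem_channels: int | None = None   # default: keep the band count
    branch_kernels: tuple[int, ...] = (3, 5, 7)
    branch_channels: int = 2
    pool: int = 4
    se_reduction: int = 2
    fc_dims: tuple[int, int] = (512, 256)
    n_classes: int = 2
    se_placement: str = "after_branches"  # or "before_branches"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if any(k % 2 == 0 for k in self.branch_kernels):
            raise ValueError("branch kernel sizes must be odd")
        if self.se_placement not in ("after_branches", "before_branches"):
            raise ValueError("se_placement must be after_branches or before_branches")

    @property
    def multi_scale(self) -> bool:
        return self.variant in ("mscnn", "mssecnn")

    @property
    def with_se(self) -> bool:
        return self.variant in ("secnn", "mssecnn")


@dataclass
class ModelHandle:
    """A built (possibly trained) classifier: layers + forward map to probabilities."""

    cfg: ModelConfig
    layers: list[Layer]
    seed: int

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of H x W x C tensors (N, H, W, C)."""
        h = np.asarray(X, dtype=DTYPE)
        if h.ndim == 3:
            h = h[None]
        for layer in self.layers:
            h = layer.forward(h)
        return _softmax(h)

    predict_proba = forward

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).argmax(axis=1)

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def train_step_backward(self, probs: np.ndarray, y: np.ndarray) -> None:
        """Backprop of mean cross-entropy given forward() output probs."""
        n = len(y)
        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        d /= n
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build_model(cfg: ModelConfig, seed: int = 0) -> ModelHandle:
    """Construct a seeded, reproducibly initialised classifier variant.

    Geometry with defaults: 16x16xC input -> 1x1 conv stem (C channels) ->
    branch convs keep 16x16, 2 channels each -> 4x4 pool -> 4x4x2 maps ->
    concat 4x4x6 (three branches) or 4x4x2 (one) -> [SE] -> FC 512/256 ->
    softmax over n_classes.
    """
    rng = np.random.default_rng(seed)
    c_in = cfg.in_channels
    stem_c = cfg.stem_channels or c_in
    layers: list[Layer] = [Conv2dSame(1, c_in, stem_c, rng)]

    if cfg.with_se and cfg.se_placement == "before_branches":
        layers.append(SEBlock(stem_c, _feasible_r(stem_c, cfg.se_reduction), rng))

    kernels = cfg.branch_kernels if cfg.multi_scale else cfg.branch_kernels[:1]
    branches = [
        [Conv2dSame(k, stem_c, cfg.branch_channels, rng), ReLU(), MaxPool(cfg.pool)]
        for k in kernels
    ]
    layers.append(ParallelConcat(branches))
    concat_c = cfg.branch_channels * len(kernels)

    if cfg.with_se and cfg.se_placement == "after_branches":
        layers.append(SEBlock(concat_c, cfg.se_reduction, rng))

    h, w = cfg.input_hw
    if h % cfg.pool or w % cfg.pool:
        raise ValueError("input spatial dims must be divisible by the pool size")
    flat = (h // cfg.pool) * (w // cfg.pool) * concat_c
    layers.append(Flatten())
    d = flat
    for fc in cfg.fc_dims:
        layers += [Dense(d, fc, rng), ReLU()]
        d = fc
    layers.append(Dense(d, cfg.n_classes, rng))
    return ModelHandle(cfg=cfg, layers=layers, seed=seed)


def _feasible_r(c: int, r: int) -> int:
    """Largest divisor of c not exceeding r (keeps C/r an integer >= 1)."""
    for cand in range(min(r, c), 0, -1):
        if c % cand == 0:
            return cand
    return 1


def count_params(h: ModelHandle) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.size for p in h.parameters()))
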