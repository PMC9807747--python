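"""Minimal convolutional-network engine for window classification.

The detection and masking networks are small four-conv-layer classifiers on
50x50 single-channel windows.  This module implements exactly the pieces
those networks need — valid convolution, batch normalisation, ReLU, 2x2 max
pooling, fully-connected layers, softmax cross-entropy and SGD with momentum
— on plain numpy arrays, in float32, with all randomness drawn from an
explicit Generator so training is reproducible bit-for-bit.

Two evaluation paths are provided and kept numerically identical:

* :meth:`Network.predict_proba` — batched per-window forward pass;
* :func:`sliding_response` — a dense ("a trous") evaluation that computes
  the stride-1 sliding-window response over a whole image by sharing
  convolution work between overlapping windows.  Max pooling introduces a
  2x2 phase ambiguity, so pooled feature maps are branched per phase; every
  individual dot product and max is the same as in the per-window pass, so
  the two paths agree exactly, not just to tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import as_strided

DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col helpers

def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N * Ho * Wo, C * k * k) patch matrix, (C, ky, kx) order."""
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    s0, s1, s2, s3 = x.strides
    view = as_strided(
        x, shape=(n, c, ho, wo, k, k), strides=(s0, s1, s2, s3, s2, s3)
    )
    # (N, Ho, Wo, C, k, k) so each row is one receptive field
    return np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )


_MM_BLOCK = 512


def mm_eval(a: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``a @ w.T + b`` computed in fixed 512-row blocks (last block padded).

    BLAS picks different kernels — with different floating-point summation
    orders — depending on the number of rows, so the same dot product can
    give last-ulp-different results in a batched call versus a single-row
    call.  Processing every inference matmul in blocks of exactly 512 rows
    makes each row's result a pure function of that row and the weights,
    which is what lets the dense sliding evaluation and the per-window
    forward pass agree bit-for-bit.
    """
    m, k = a.shape
    out = np.empty((m, w.shape[0]), dtype=a.dtype)
    for i in range(0, m, _MM_BLOCK):
        blk = a[i:i + _MM_BLOCK]
        if blk.shape[0] < _MM_BLOCK:
            pad = np.zeros((_MM_BLOCK, k), dtype=a.dtype)
            pad[: blk.shape[0]] = blk
            out[i:] = (pad @ w.T + b)[: blk.shape[0]]
        else:
            out[i:i + _MM_BLOCK] = blk @ w.T + b
    return out


# ---------------------------------------------------------------------------
# layers

class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Valid (no-padding) stride-1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 first: bool = False):
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.first = first          # first layer skips input gradient
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        cols = im2col(x, self.k)
        if train:
            self._cols = cols
            out = cols @ self.w.T + self.b
        else:
            out = mm_eval(cols, self.w, self.b)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, f, ho, wo = g.shape
        gm = g.transpose(0, 2, 3, 1).reshape(-1, f)
        self.grads[0][...] = gm.T @ self._cols
        self.grads[1][...] = gm.sum(axis=0)
        self._cols = None
        if self.first:
            return None
        dcols = gm @ self.w                                   # (N*Ho*Wo, C*k*k)
        k, c = self.k, self.in_ch
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for ky in range(k):
            for kx in range(k):
                dx[:, :, ky:ky + ho, kx:kx + wo] += dcols[:, :, :, :, ky, kx].transpose(0, 3, 1, 2)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation (conv -> BN -> ReLU ordering)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=DTYPE)
        self.beta = np.zeros(ch, dtype=DTYPE)
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def _bcast(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if not train:
            # folded per-channel affine; the same expression the dense
            # sliding evaluator uses, so both paths agree bit-for-bit
            scale, shift = self.eval_affine()
            return x * self._bcast(scale, x.ndim) + self._bcast(shift, x.ndim)
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        m = self.momentum
        self.running_mean[...] = (1 - m) * self.running_mean + m * mean
        self.running_var[...] = (1 - m) * self.running_var + m * var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bcast(mean, x.ndim)) * self._bcast(inv, x.ndim)
        if train:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._count = x.size // x.shape[1]
        return xhat * self._bcast(self.gamma, x.ndim) + self._bcast(self.beta, x.ndim)

    def eval_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (scale, shift) equivalent of the eval-mode transform."""
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma * inv
        return scale, self.beta - self.running_mean * scale

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = self._axes
        nd = g.ndim
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        m = self._count
        gx = (g * self._bcast(self.gamma, nd)
              - self._bcast(self.grads[1] / m * self.gamma, nd)
              - self._xhat * self._bcast(self.grads[0] / m * self.gamma, nd))
        gx *= self._bcast(self._inv, nd)
        self._xhat = None
        return gx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor on odd sizes."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        patches = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
        if train:
            self._arg = patches.argmax(axis=-1)
            self._in_shape = x.shape
        return patches.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = g.shape
        onehot = np.eye(4, dtype=DTYPE)[self._arg]            # (n,c,h2,w2,4)
        grad = (g[..., None] * onehot).reshape(n, c, h2, w2, 2, 2)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, :, : 2 * h2, : 2 * w2] = grad.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, 2 * h2, 2 * w2
        )
        self._arg = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
            return x @ self.w.T + self.b
        return mm_eval(x, self.w, self.b)

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = g.T @ self._x
        self.grads[1][...] = g.sum(axis=0)
        dx = g @ self.w
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# network

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain sequential network with softmax cross-entropy on top."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        """Class probabilities, evaluated in eval mode, in batches."""
        out = []
        for i in range(0, len(x), batch):
            out.append(softmax(self.forward(x[i:i + batch].astype(DTYPE), train=False)))
        return np.concatenate(out, axis=0)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Softmax cross-entropy forward + full backward pass."""
        logits = self.forward(x, train=True)
        p = softmax(logits)
        n = len(y)
        loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
        g = p.astype(DTYPE)
        g[np.arange(n), y] -= 1.0
        g /= DTYPE(n)
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break
        return loss

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(getattr(layer, "params", [])):
                state[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm):
                state[f"layer{i}_rmean"] = layer.running_mean
                state[f"layer{i}_rvar"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(getattr(layer, "params", [])):
                p[...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}_rmean"]
                layer.running_var[...] = state[f"layer{i}_rvar"]


@dataclass
class SGDMomentum:
    lr: float = 0.01
    momentum: float = 0.9

    def __post_init__(self):
        self._velocity: dict[int, np.ndarray] = {}

    def step(self, net: Network) -> None:
        for layer in net.layers:
            for p, g in zip(getattr(layer, "params", []), getattr(layer, "grads", [])):
                key = id(p)
                v = self._velocity.get(key)
                if v is None:
                    v = self._velocity[key] = np.zeros_like(p)
                v *= DTYPE(self.momentum)
                v -= DTYPE(self.lr) * g
                p += v


@dataclass
class TrainingHistory:
    """Per-epoch training loss and held-out accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float | None] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def fit(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    rng: np.random.Generator,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 128,
    lr_decay_epochs: tuple[int, ...] = (),
    lr_decay_factor: float = 0.1,
    verbose: bool = False,
) -> TrainingHistory:
    """Train with shuffled mini-batch SGD; record loss and held-out accuracy.

    ``lr_decay_epochs`` lists epoch indices (0-based) at whose start the
    learning rate is multiplied by ``lr_decay_factor`` — the usual step
    schedule for squeezing out boundary-precision late in training.
    """
    opt = SGDMomentum(lr=lr, momentum=momentum)
    hist = TrainingHistory()
    x = x.astype(DTYPE)
    have_val = x_val is not None and len(x_val) > 0
    if not have_val:
        hist.warnings.append("no holdout: accuracy not tracked")
    for epoch in range(epochs):
        if epoch in lr_decay_epochs:
            opt.lr *= lr_decay_factor
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), batch_size):
            idx = order[i:i + batch_size]
            if len(idx) < 2:
                continue            # BatchNorm needs at least 2 samples
            losses.append(net.loss_and_backward(x[idx], y[idx]))
            opt.step(net)
        hist.loss.append(float(np.mean(losses)))
        if have_val:
            pred = net.predict_proba(x_val).argmax(axis=1)
            hist.accuracy.append(float((pred == y_val).mean()))
        else:
            hist.accuracy.append(None)
        if verbose:
            acc = hist.accuracy[-1]
            msg = f"epoch {epoch + 1}/{epochs} loss {hist.loss[-1]:.4f}"
            if acc is not None:
                msg += f" holdout_acc {acc:.4f}"
            print(msg)
    return hist


# ---------------------------------------------------------------------------
# dense sliding-window evaluation

def sliding_response(net: Network, image: np.ndarray, window: int = 50) -> np.ndarray:
    """Stride-1 sliding-window probability map over ``image``.

    Returns an array of shape ``(H - window + 1, W - window + 1)`` whose
    entry (i, j) is the particle-class probability of the window with
    top-left corner (i, j), bit-identical to classifying each window with
    :meth:`Network.predict_proba`.
    """
    img = np.asarray(image, dtype=DTYPE)
    h, w = img.shape
    if h < window or w < window:
        raise ValueError(f"image {h}x{w} smaller than window {window}")
    out_h, out_w = h - window + 1, w - window + 1

    # phases: list of (feature map (C, Hm, Wm), stride, offset (oy, ox))
    phases: list[tuple[np.ndarray, int, tuple[int, int]]] = [
        (img[None, :, :], 1, (0, 0))
    ]
    layers = net.layers
    i = 0
    local = window                       # spatial size of the window's own grid
    while not isinstance(layers[i], Flatten):
        layer = layers[i]
        if isinstance(layer, Conv2d):
            new = []
            for fmap, s, off in phases:
                cols = im2col(fmap[None], layer.k)
                hm, wm = fmap.shape[1] - layer.k + 1, fmap.shape[2] - layer.k + 1
                outm = mm_eval(cols, layer.w, layer.b).reshape(hm, wm, layer.out_ch)
                new.append((outm.transpose(2, 0, 1), s, off))
            phases = new
            local = local - layer.k + 1
        elif isinstance(layer, BatchNorm):
            scale, shift = layer.eval_affine()
            phases = [
                (fmap * scale[:, None, None] + shift[:, None, None], s, off)
                for fmap, s, off in phases
            ]
        elif isinstance(layer, ReLU):
            phases = [(np.maximum(fmap, 0), s, off) for fmap, s, off in phases]
        elif isinstance(layer, MaxPool2):
            new = []
            for fmap, s, off in phases:
                for py in (0, 1):
                    for px in (0, 1):
                        sub = fmap[:, py:, px:]
                        c, hs, ws = sub.shape
                        h2, w2 = hs // 2, ws // 2
                        if h2 == 0 or w2 == 0:
                            continue
                        pooled = (
                            sub[:, : 2 * h2, : 2 * w2]
                            .reshape(c, h2, 2, w2, 2)
                            .max(axis=(2, 4))
                        )
                        new.append((pooled, 2 * s, (off[0] + py * s, off[1] + px * s)))
            phases = new
            local = local // 2
        else:  # pragma: no cover - unknown layer in conv tower
            raise TypeError(f"unsupported layer in conv tower: {type(layer)}")
        i += 1

    # head: Flatten then Dense/ReLU stack
    head = layers[i + 1:]
    result = np.full((out_h, out_w), np.nan, dtype=DTYPE)
    for fmap, s, off in phases:
        c, hm, wm = fmap.shape
        n_my, n_mx = hm - local + 1, wm - local + 1
        if n_my <= 0 or n_mx <= 0:
            continue
        s0, s1, s2 = fmap.strides
        view = as_strided(
            fmap,
            shape=(n_my, n_mx, c, local, local),
            strides=(s1, s2, s0, s1, s2),
        )
        feats = np.ascontiguousarray(view).reshape(n_my * n_mx, c * local * local)
        z = feats
        for layer in head:
            if isinstance(layer, Dense):
                z = mm_eval(z, layer.w, layer.b)
            elif isinstance(layer, ReLU):
                z = np.maximum(z, 0)
            else:  # pragma: no cover
                raise TypeError(f"unsupported head layer: {type(layer)}")
        probs = softmax(z)[:, 1].reshape(n_my, n_mx)
        oy, ox = off
        ys = oy + s * np.arange(n_my)
        xs = ox + s * np.arange(n_mx)
        keep_y = ys < out_h
        keep_x = xs < out_w
        result[np.ix_(ys[keep_y], xs[keep_x])] = probs[np.ix_(keep_y, keep_x)]
    assert not np.isnan(result).any(), "sliding evaluation left uncovered positions"
    return result
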