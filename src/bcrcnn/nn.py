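"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the detector needs — dense and
3x3 convolutional layers, 2x2 max pooling, nearest-neighbour up/down
sampling, weighted gathers (the differentiable half of ROI align), the
classification/regression losses, and an SGD-with-momentum optimizer.  It is
deliberately small: single-image batches, float32, stride-1 'same'
convolutions only.  Everything is deterministic given the RNG used for
initialization.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "mul", "matmul", "relu", "reshape",
    "concat", "take_rows", "conv2d", "max_pool2x", "upsample2x",
    "subsample2", "weighted_gather", "softmax_t", "sigmoid_t",
    "nll_loss", "bce_probs", "smooth_l1", "stop_gradient", "softmax",
    "Conv2d", "Linear", "SGD",
]


class Tensor:
    """A numpy array plus the closure that backpropagates through it."""

    __slots__ = ("data", "grad", "parents", "grad_fn")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn  # grad_out -> tuple of grads, aligned with parents
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad_fn is None or node.grad is None:
                continue
            grads = node.grad_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data * b.data, (a, b),
                  lambda g: (_unbroadcast(g * b.data, a.data.shape),
                             _unbroadcast(g * a.data, b.data.shape)))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data @ b.data, (a, b),
                  lambda g: (g @ b.data.T, a.data.T @ g))


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    old = x.data.shape
    return Tensor(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def concat(xs, axis=0) -> Tensor:
    xs = [as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]
    return Tensor(np.concatenate([x.data for x in xs], axis=axis), tuple(xs),
                  lambda g: tuple(np.split(g, splits, axis=axis)))


def take_rows(x, idx) -> Tensor:
    """Select rows x[idx] along axis 0; backward scatter-adds."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return Tensor(x.data[idx], (x,), bwd)


def stop_gradient(x) -> Tensor:
    x = as_tensor(x)
    return Tensor(x.data.copy())


# ---------------------------------------------------------------------------
# convolution / pooling / resampling


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """'Same' padded patches of x (N,C,H,W) -> (N*H*W, C*kh*kw)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (N,C,H,W,kh,kw) -> (N,H,W,C,kh,kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)


def _col2im(gcols: np.ndarray, shape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    gxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=gcols.dtype)
    g = gcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i:i + h, j:j + w] += g[:, :, i, j]
    return gxp[:, :, ph:ph + h, pw:pw + w]


def conv2d(x, weight, bias) -> Tensor:
    """Stride-1 'same' convolution. x: (N,C,H,W); weight: (F,C,kh,kw); bias: (F,)."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    n, c, h, w = x.data.shape
    f, _, kh, kw = weight.data.shape
    cols = _im2col(x.data, kh, kw)
    w2 = weight.data.reshape(f, -1)
    out = (cols @ w2.T + bias.data).reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def bwd(g):
        gf = g.transpose(0, 2, 3, 1).reshape(-1, f)
        gw = (gf.T @ cols).reshape(weight.data.shape)
        gb = gf.sum(axis=0)
        gx = _col2im(gf @ w2, x.data.shape, kh, kw)
        return gx, gw, gb

    return Tensor(out, (x, weight, bias), bwd)


def max_pool2x(x) -> Tensor:
    """2x2 max pooling, stride 2; requires even spatial dims."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(n, c, h, w),)

    return Tensor(out, (x,), bwd)


def upsample2x(x) -> Tensor:
    """Nearest-neighbour 2x upsampling of (N,C,H,W)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor(out, (x,), bwd)


def subsample2(x) -> Tensor:
    """Stride-2 spatial subsampling (top-left sample of each 2x2 block)."""
    x = as_tensor(x)

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, :, ::2, ::2] = g
        return (gx,)

    return Tensor(x.data[:, :, ::2, ::2], (x,), bwd)


def weighted_gather(x, idx, weights) -> Tensor:
    """out[s] = sum_j weights[s,j] * x[idx[s,j]] for row-major features.

    x: (L, C) tensor (flattened spatial positions by channel); idx: (S, J)
    integer array; weights: (S, J) constants.  This is the differentiable
    kernel underneath bilinear ROI sampling.
    """
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    wts = np.asarray(weights, dtype=np.float32)
    xd = x.data
    out = np.zeros((idx.shape[0], xd.shape[1]), dtype=np.float32)
    for j in range(idx.shape[1]):
        out += xd[idx[:, j]] * wts[:, j:j + 1]

    def bwd(g):
        gx = np.zeros_like(xd)
        for j in range(idx.shape[1]):
            np.add.at(gx, idx[:, j], g * wts[:, j:j + 1])
        return (gx,)

    return Tensor(out, (x,), bwd)


# ---------------------------------------------------------------------------
# losses


def softmax(logits: np.ndarray, axis=-1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_t(logits) -> Tensor:
    """Differentiable row softmax over the last axis."""
    logits = as_tensor(logits)
    p = softmax(logits.data.astype(np.float64))

    def bwd(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        return ((p * (g - dot)).astype(np.float32),)

    return Tensor(p, (logits,), bwd)


def sigmoid_t(logits) -> Tensor:
    logits = as_tensor(logits)
    p = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    return Tensor(p, (logits,), lambda g: ((g * p * (1 - p)).astype(np.float32),))


_EPS = 1e-7


def nll_loss(probs, labels, normalizer=None) -> Tensor:
    """Cross-entropy -mean log p[label] on probability rows (N, K).

    Exactly zero for one-hot correct predictions.
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=np.intp)
    n = probs.data.shape[0]
    norm = float(normalizer) if normalizer is not None else float(max(n, 1))
    p = np.clip(probs.data[np.arange(n), labels].astype(np.float64), _EPS, 1.0)
    loss = -np.log(p).sum() / norm

    def bwd(g):
        gp = np.zeros(probs.data.shape, dtype=np.float64)
        gp[np.arange(n), labels] = -g / (p * norm)
        return (gp.astype(np.float32),)

    return Tensor(loss, (probs,), bwd)


def bce_probs(probs, targets, normalizer=None) -> Tensor:
    """Binary cross-entropy on probabilities (N,); zero at exact targets."""
    probs = as_tensor(probs)
    t = np.asarray(targets, dtype=np.float64)
    n = probs.data.shape[0]
    norm = float(normalizer) if normalizer is not None else float(max(n, 1))
    p = probs.data.astype(np.float64)
    pp = np.clip(p, _EPS, 1.0)        # used by the t side
    pn = np.clip(1.0 - p, _EPS, 1.0)  # used by the (1-t) side
    loss = -(t * np.log(pp) + (1 - t) * np.log(pn)).sum() / norm

    def bwd(g):
        gp = g * (-(t / pp) + (1 - t) / pn) / norm
        return (gp.astype(np.float32),)

    return Tensor(loss, (probs,), bwd)


def smooth_l1(pred, target, normalizer, beta: float = 1.0) -> Tensor:
    """Huber/smooth-L1 summed over elements, divided by `normalizer`."""
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=np.float64)
    d = pred.data.astype(np.float64) - t
    ad = np.abs(d)
    quad = ad < beta
    loss = np.where(quad, 0.5 * d * d / beta, ad - 0.5 * beta).sum() / float(normalizer)

    def bwd(g):
        gd = np.where(quad, d / beta, np.sign(d)) / float(normalizer)
        return ((g * gd).astype(np.float32),)

    return Tensor(loss, (pred,), bwd)


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: tracks parameters of itself and child modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor):
                        out.append((f"{name}.{i}", item))
        return out


class Conv2d(Module):
    """3x3 (or kxk) same-padding convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.bias = Tensor(np.zeros(out_ch))

    def __call__(self, x) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 std: float | None = None):
        std = std if std is not None else np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, size=(in_f, out_f)))
        self.bias = Tensor(np.zeros(out_f))

    def __call__(self, x) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, v, g in zip(self.params, self.velocity, grads):
            g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
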