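"""Reverse-mode automatic differentiation on NumPy arrays.

This is the compute core behind every neural model in the package: dense
stacks, message passing over sparse adjacency, edge-wise attention softmax,
and the loss menu. Everything runs in float64 so that gradients can be
validated against central finite differences to tight tolerances.

Only the operations the models need are implemented; sparse matrices and
integer index arrays are always treated as constants (no gradient flows
into graph structure).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "exp", "matmul", "spmm",
    "leaky_relu", "relu", "gather", "segment_sum", "segment_max",
    "sum_all", "mean_all", "row_sum", "concat_cols", "scale", "reshape",
    "segment_softmax",
    "softmax_cross_entropy", "bce_with_logits", "mse_loss", "censored_mse",
    "Dense", "Adam", "ReduceLROnPlateau", "uniform_init",
]


class Tensor:
    """A node in the computation graph holding a float64 ndarray."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self.parents
        )
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    def backward(self):
        """Accumulate gradients of this (scalar or full-ones seeded) output."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:  # out-of-place: the first gradient may alias a child's
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    a, b = _t(a), _t(b)
    return Tensor(
        a.value + b.value, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    a, b = _t(a), _t(b)
    return Tensor(
        a.value - b.value, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def neg(a):
    a = _t(a)
    return Tensor(-a.value, (a,), lambda g: (-g,))


def mul(a, b):
    a, b = _t(a), _t(b)
    return Tensor(
        a.value * b.value, (a, b),
        lambda g: (
            _unbroadcast(g * b.value, a.shape),
            _unbroadcast(g * a.value, b.shape),
        ),
    )


def div(a, b):
    a, b = _t(a), _t(b)
    return Tensor(
        a.value / b.value, (a, b),
        lambda g: (
            _unbroadcast(g / b.value, a.shape),
            _unbroadcast(-g * a.value / b.value ** 2, b.shape),
        ),
    )


def scale(a, c: float):
    a = _t(a)
    return Tensor(a.value * c, (a,), lambda g: (g * c,))


def exp(a):
    a = _t(a)
    out_val = np.exp(a.value)
    return Tensor(out_val, (a,), lambda g: (g * out_val,))


def matmul(a, b):
    a, b = _t(a), _t(b)
    return Tensor(
        a.value @ b.value, (a, b),
        lambda g: (g @ b.value.T, a.value.T @ g),
    )


def spmm(A: sp.spmatrix, x):
    """Sparse (constant) @ dense (differentiable)."""
    x = _t(x)
    A = A.tocsr()
    return Tensor(A @ x.value, (x,), lambda g: (A.T @ g,))


def leaky_relu(a, slope: float = 0.1):
    a = _t(a)
    neg = a.value <= 0
    out = a.value.copy()
    out[neg] *= slope

    def back(g):
        gg = g.copy()
        gg[neg] *= slope
        return (gg,)

    return Tensor(out, (a,), back)


def relu(a):
    a = _t(a)
    mask = (a.value > 0).astype(np.float64)
    return Tensor(a.value * mask, (a,), lambda g: (g * mask,))


def gather(a, idx):
    a = _t(a)
    idx = np.asarray(idx)

    def back(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(a.value[idx], (a,), back)


def segment_sum(a, idx, n: int):
    """Scatter-add rows of ``a`` into ``n`` segments given by ``idx``."""
    a = _t(a)
    idx = np.asarray(idx)
    shape = (n,) + a.value.shape[1:]
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, a.value)
    return Tensor(out, (a,), lambda g: (g[idx],))


def segment_max(a, idx, n: int, fill: float = 0.0):
    """Per-segment maximum; empty segments take ``fill``.

    The gradient is routed to the first row attaining the maximum in each
    segment (ties broken by position).
    """
    a = _t(a)
    idx = np.asarray(idx)
    shape = (n,) + a.value.shape[1:]
    out = np.full(shape, -np.inf)
    np.maximum.at(out, idx, a.value)
    empty = ~np.isfinite(out)
    out[empty] = fill
    # winner mask: first occurrence of the per-segment max
    is_max = a.value == out[idx]
    winner = np.zeros_like(is_max)
    taken = np.zeros(shape, dtype=bool)
    order = np.argsort(idx, kind="stable")
    for r in order:
        cand = is_max[r] & ~taken[idx[r]]
        winner[r] = cand
        taken[idx[r]] |= cand

    def back(g):
        return (g[idx] * winner,)

    return Tensor(out, (a,), back)


def sum_all(a):
    a = _t(a)
    return Tensor(a.value.sum(), (a,), lambda g: (np.full_like(a.value, g),))


def mean_all(a):
    a = _t(a)
    n = a.value.size
    return Tensor(a.value.mean(), (a,), lambda g: (np.full_like(a.value, g / n),))


def row_sum(a):
    """Sum over the last axis, keeping a 1-D result for 2-D input."""
    a = _t(a)
    return Tensor(
        a.value.sum(axis=-1), (a,),
        lambda g: (np.broadcast_to(g[..., None], a.shape).copy(),),
    )


def reshape(a, shape):
    a = _t(a)
    return Tensor(a.value.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def concat_cols(tensors):
    tensors = [_t(t) for t in tensors]
    widths = [t.value.shape[1] for t in tensors]
    splits = np.cumsum(widths)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=1))

    return Tensor(np.concatenate([t.value for t in tensors], axis=1), tuple(tensors), back)


def segment_softmax(scores: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of a 1-D score vector within segments.

    The per-segment maximum is subtracted (as a constant) before
    exponentiation for numerical stability; this is also the documented
    transformation of the attention scores.
    """
    seg = np.asarray(seg)
    m = np.full(n_seg, -np.inf)
    if len(seg):
        np.maximum.at(m, seg, scores.value)
    m[~np.isfinite(m)] = 0.0
    e = exp(sub(scores, Tensor(m[seg])))
    denom = segment_sum(e, seg, n_seg)
    return div(e, gather(denom, seg))


# ---------------------------------------------------------------------------
# fused losses


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Categorical cross-entropy with integer class labels, mean over rows."""
    labels = np.asarray(labels, dtype=int)
    z = logits.value
    zmax = z.max(axis=1, keepdims=True)
    logsum = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsum
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def back(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    return Tensor(loss, (logits,), back)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Binary cross-entropy with logits for proportion targets, mean over entries."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.value
    # log(1 + e^{-|z|}) formulation for stability
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    sig = 1.0 / (1.0 + np.exp(-z))
    n = z.size

    def back(g):
        return (g * (sig - t) / n,)

    return Tensor(loss, (logits,), back)


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    t = np.asarray(targets, dtype=np.float64)
    diff = pred.value - t
    n = diff.size

    def back(g):
        return (g * 2.0 * diff / n,)

    return Tensor((diff ** 2).mean(), (pred,), back)


def censored_mse(pred: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Right-censored squared error on predicted event times.

    Events contribute the usual squared error; censored subjects contribute a
    one-sided hinge: a prediction beyond the censoring time costs nothing,
    undershooting it costs the squared gap. Each part is averaged over its own
    subjects.
    """
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events)
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    e = e.astype(bool)
    p = pred.value.reshape(-1)
    grad = np.zeros_like(p)
    loss = 0.0
    if e.any():
        d = p[e] - t[e]
        loss += (d ** 2).mean()
        grad[e] = 2.0 * d / e.sum()
    if (~e).any():
        h = np.maximum(0.0, t[~e] - p[~e])
        loss += (h ** 2).mean()
        grad[~e] = -2.0 * h / (~e).sum()

    def back(g):
        return (g * grad.reshape(pred.shape),)

    return Tensor(loss, (pred,), back)


# ---------------------------------------------------------------------------
# layers and optimization


def uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    limit = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """A fully connected layer ``x @ W (+ b)`` with optional leaky-ReLU."""

    def __init__(self, rng, d_in, d_out, bias=True, activation=True, slope=0.1):
        self.W = Tensor(uniform_init(rng, (d_in, d_out), d_in), requires_grad=True)
        self.b = Tensor(uniform_init(rng, (d_out,), d_in), requires_grad=True) if bias else None
        self.activation = activation
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.W)
        if self.b is not None:
            out = add(out, self.b)
        if self.activation:
            out = leaky_relu(out, self.slope)
        return out

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params, lr=5e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer, factor=0.5, patience=10, min_lr=1e-5):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
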