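"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the untrained generator network and the
plug-and-play loss need: 2-D convolution (im2col), leaky ReLU, 2x average
pooling, 2x bilinear upsampling, channel concatenation, padding/cropping,
and elementwise arithmetic, plus an Adam optimizer.  Images are laid out
channels-first, (C, H, W), one image at a time.

Every op builds a node holding, per parent, a closure that maps the
output gradient to that parent's gradient contribution; ``backward`` runs
a topological sweep.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "leaky_relu", "avg_pool2", "upsample_bilinear2",
           "concat", "pad2d", "crop2d", "square_sum", "Adam"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self._parents = parents if self.requires_grad else ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p, _ in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._parents:
                for p, fn in node._parents:
                    if not p.requires_grad:
                        continue
                    contrib = fn(g)
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + contrib
                    else:
                        grads[id(p)] = contrib
            else:
                node.grad = g if node.grad is None else node.grad + g

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        return Tensor(self.data + other.data,
                      parents=((self, lambda g: g), (other, lambda g: g)))

    __radd__ = __add__

    def __sub__(self, other):
        other = _wrap(other)
        return Tensor(self.data - other.data,
                      parents=((self, lambda g: g), (other, lambda g: -g)))

    def __rsub__(self, other):
        return _wrap(other) - self

    def __mul__(self, other):
        other = _wrap(other)
        a, b = self.data, other.data
        return Tensor(a * b,
                      parents=((self, lambda g: g * b), (other, lambda g: g * a)))

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def sum(self):
        shape = self.data.shape
        return Tensor(self.data.sum(),
                      parents=((self, lambda g: np.broadcast_to(g, shape).copy()),))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def square_sum(x: Tensor) -> Tensor:
    """sum(x**2) as a single fused node."""
    d = x.data
    return Tensor(np.sum(d * d), parents=((x, lambda g: g * 2.0 * d),))


# -- neural-network ops ----------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)
    return Tensor(out, parents=((x, lambda g: np.where(mask, g, slope * g)),))


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int | None = None) -> Tensor:
    """2-D convolution (cross-correlation), channels-first single image.

    x: (Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,).  ``pad`` defaults to
    k//2 (same-size output at stride 1).
    """
    cout, cin, k, _ = w.shape
    if pad is None:
        pad = k // 2
    xd = x.data
    xp = np.pad(xd, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    _, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(ho * wo, cin * k * k)
    wm = w.data.reshape(cout, cin * k * k)
    out = (cols @ wm.T + b.data).reshape(ho, wo, cout).transpose(2, 0, 1)

    def grad_x(g):
        gmat = g.transpose(1, 2, 0).reshape(ho * wo, cout)
        gcols = (gmat @ wm).reshape(ho, wo, cin, k, k)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                gxp[:, di:di + ho * stride:stride, dj:dj + wo * stride:stride] += \
                    gcols[:, :, :, di, dj].transpose(2, 0, 1)
        if pad:
            return gxp[:, pad:-pad, pad:-pad]
        return gxp

    def grad_w(g):
        gmat = g.transpose(1, 2, 0).reshape(ho * wo, cout)
        return (gmat.T @ cols).reshape(w.shape)

    def grad_b(g):
        return g.sum(axis=(1, 2))

    return Tensor(out, parents=((x, grad_x), (w, grad_w), (b, grad_b)))


def avg_pool2(x: Tensor) -> Tensor:
    c, h, w = x.data.shape
    out = x.data.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))

    def grad(g):
        return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25

    return Tensor(out, parents=((x, grad),))


def _up1d(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    out = np.empty((2 * n,) + a.shape[1:], dtype=a.dtype)
    out[0] = a[0]
    out[2::2] = 0.25 * a[:-1] + 0.75 * a[1:]
    out[1:-1:2] = 0.75 * a[:-1] + 0.25 * a[1:]
    out[-1] = a[-1]
    return np.moveaxis(out, 0, axis)


def _up1d_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    n = g.shape[0] // 2
    ga = np.zeros((n,) + g.shape[1:], dtype=g.dtype)
    ga[0] += g[0]
    ga[-1] += g[-1]
    ge = g[2::2]
    ga[:-1] += 0.25 * ge
    ga[1:] += 0.75 * ge
    go = g[1:-1:2]
    ga[:-1] += 0.75 * go
    ga[1:] += 0.25 * go
    return np.moveaxis(ga, 0, axis)


def upsample_bilinear2(x: Tensor) -> Tensor:
    """2x bilinear upsampling (half-pixel aligned); backward is the exact adjoint."""
    out = _up1d(_up1d(x.data, 1), 2)

    def grad(g):
        return _up1d_adjoint(_up1d_adjoint(g, 2), 1)

    return Tensor(out, parents=((x, grad),))


def concat(parts: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [p.data.shape[0] for p in parts]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([p.data for p in parts], axis=0)

    def make_grad(i):
        lo, hi = offsets[i], offsets[i + 1]
        return lambda g: g[lo:hi]

    return Tensor(out, parents=tuple((p, make_grad(i)) for i, p in enumerate(parts)))


def pad2d(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the bottom/right so H and W hit a multiple of the net stride."""
    out = np.pad(x.data, ((0, 0), (0, pad_h), (0, pad_w)))
    h, w = x.data.shape[1:]
    return Tensor(out, parents=((x, lambda g: g[:, :h, :w]),))


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    ph = x.data.shape[1] - h
    pw = x.data.shape[2] - w

    def grad(g):
        return np.pad(g, ((0, 0), (0, ph), (0, pw)))

    return Tensor(x.data[:, :h, :w], parents=((x, grad),))


class Adam:
    """Adam over a list of parameter Tensors (float32 state)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
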