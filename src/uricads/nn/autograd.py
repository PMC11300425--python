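"""Minimal reverse-mode automatic differentiation on numpy arrays.

Tensors wrap float64 ndarrays and record a backward closure; ``backward()``
walks the graph in reverse topological order.  The op set is exactly what
the three-branch network needs: broadcast arithmetic, matmul, 2-D
convolution (im2col), nearest-neighbour x2 upsampling, elementwise
nonlinearities, reductions, gather/concat, and numerically stable
cross-entropy / smooth-L1 losses.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def gather(self, indices) -> "Tensor":
        """Select elements of a flattened tensor by integer indices."""
        idx = np.asarray(indices, dtype=int)
        flat = self.data.reshape(-1)
        out = Tensor(flat[idx], _prev=(self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(flat)
                np.add.at(g, idx, out.grad.reshape(-1))
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    # -- reductions & nonlinearities -----------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / self.data.size))

        out._backward = backward
        return out

    def mean_spatial(self) -> "Tensor":
        """Global average pooling: mean over the trailing two axes."""
        out = Tensor(self.data.mean(axis=(-2, -1)), _prev=(self,))

        def backward():
            if self.requires_grad:
                n = self.data.shape[-1] * self.data.shape[-2]
                self._accum(
                    np.broadcast_to(out.grad[..., None, None] / n, self.data.shape).copy()
                )

        out._backward = backward
        return out

    def max(self) -> "Tensor":
        """Maximum over all elements; gradient flows to the first argmax."""
        flat_idx = int(np.argmax(self.data))
        out = Tensor(self.data.reshape(-1)[flat_idx], _prev=(self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data).reshape(-1)
                g[flat_idx] = out.grad
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = np.empty_like(self.data)
        pos = self.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        s[~pos] = ex / (1.0 + ex)
        out = Tensor(s, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = backward
        return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 1-D tensors."""
    datas = [t.data.reshape(-1) for t in tensors]
    out = Tensor(np.concatenate(datas), _prev=tuple(tensors))
    offsets = np.cumsum([0] + [d.size for d in datas])

    def backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(out.grad[a:b].reshape(t.data.shape))

    out._backward = backward
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of a (C, H, W) tensor."""
    up = np.repeat(np.repeat(x.data, 2, axis=-2), 2, axis=-1)
    out = Tensor(up, _prev=(x,))

    def backward():
        if x.requires_grad:
            C, H, W = x.data.shape
            g = out.grad.reshape(C, H, 2, W, 2).sum(axis=(2, 4))
            x._accum(g)

    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution of a single (C_in, H, W) image.

    ``w`` has shape (C_out, C_in, kh, kw), ``b`` shape (C_out,).  Output is
    (C_out, H_out, W_out) with H_out = (H + 2*pad - kh)//stride + 1.
    """
    C_in, H, W = x.data.shape
    C_out, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C_in, H_out, W_out, kh, kw)
    _, H_out, W_out, _, _ = win.shape
    cols = win.transpose(1, 2, 0, 3, 4).reshape(H_out * W_out, C_in * kh * kw)
    w_mat = w.data.reshape(C_out, -1)
    y = cols @ w_mat.T + b.data
    out = Tensor(y.T.reshape(C_out, H_out, W_out), _prev=(x, w, b))

    def backward():
        dout = out.grad.reshape(C_out, H_out * W_out).T  # (HW, C_out)
        if w.requires_grad:
            w._accum((dout.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(dout.sum(axis=0))
        if x.requires_grad:
            dcols = (dout @ w_mat).reshape(H_out, W_out, C_in, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + stride * H_out : stride,
                        j : j + stride * W_out : stride] += dcols[:, :, :, i, j
                        ].transpose(2, 0, 1)
            x._accum(dxp[:, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = backward
    return out


# -- losses -----------------------------------------------------------------


def bce_with_logits(logits: Tensor, targets, weights=None,
                    reduction: str = "mean") -> Tensor:
    """Binary cross-entropy on logits, numerically stable.

    ``loss = max(z, 0) - z*t + log(1 + exp(-|z|))`` elementwise, optionally
    weighted, then reduced by mean or sum.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    elem = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    w = np.ones_like(elem) if weights is None else np.asarray(weights, dtype=float)
    if reduction == "mean":
        scale = w / max(w.sum(), 1e-12)
    elif reduction == "sum":
        scale = w
    else:
        raise ValueError(f"unknown reduction: {reduction!r}")
    out = Tensor((elem * scale).sum(), _prev=(logits,))

    def backward():
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accum(out.grad * scale * (s - t))

    out._backward = backward
    return out


def bce_prob(p: Tensor, targets, reduction: str = "sum", eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy on probabilities in [0, 1], clamped at ``eps``."""
    pc = np.clip(p.data, eps, 1.0 - eps)
    t = np.asarray(targets, dtype=np.float64)
    elem = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc))
    val = elem.mean() if reduction == "mean" else elem.sum()
    out = Tensor(val, _prev=(p,))

    def backward():
        if p.requires_grad:
            g = (pc - t) / (pc * (1.0 - pc))
            if reduction == "mean":
                g = g / pc.size
            p._accum(out.grad * g)

    out._backward = backward
    return out


def smooth_l1(pred: Tensor, targets, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss used for box regression."""
    d = pred.data - np.asarray(targets, dtype=np.float64)
    absd = np.abs(d)
    elem = np.where(absd < beta, 0.5 * d * d / beta, absd - 0.5 * beta)
    out = Tensor(elem.mean(), _prev=(pred,))

    def backward():
        if pred.requires_grad:
            g = np.where(absd < beta, d / beta, np.sign(d)) / d.size
            pred._accum(out.grad * g)

    out._backward = backward
    return out
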