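"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the operations the fusion network needs are
implemented (broadcast arithmetic, matmul, softmax building blocks, slicing,
reshaping, a strided 3D convolution).  Everything is float64 and
single-threaded, so identical seeds give bit-identical traces.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "softmax", "conv3d"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def backward(grad, out):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad, out):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.multiply.outer(grad, b) if a.ndim > 1 else grad * b
                gb = (a * grad[..., None]).reshape(-1, b.shape[0]).sum(0) if a.ndim > 1 else a * grad
            elif a.ndim == 1:
                ga = (grad[..., None, :] * b).sum(-1)
                gb = np.multiply.outer(a, grad) if grad.ndim == 1 else None
                if gb is None:
                    gb = a[:, None] * grad
                gb = _unbroadcast(gb, b.shape)
                ga = _unbroadcast(ga, a.shape)
            else:
                ga = np.matmul(grad, np.swapaxes(b, -1, -2))
                gb = np.matmul(np.swapaxes(a, -1, -2), grad)
                ga = _unbroadcast(ga, a.shape)
                gb = _unbroadcast(gb, b.shape)
            return ga, gb

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, out):
            return (grad * out.data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(grad, out):
            return (grad / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad, out):
            return (grad * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(grad, out):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims=False) -> "Tensor":
        """Max treated as a constant (used for numerically stable softmax)."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # -- shape manipulation -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(grad, out):
            return (grad.reshape(old),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(grad, out):
            return (grad.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        def backward(grad, out):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            return (g,)

        return Tensor._make(self.data[idx], (self,), backward)

    def broadcast_to(self, shape):
        def backward(grad, out):
            return (_unbroadcast(grad, self.shape),)

        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,), backward)

    # -- backward pass ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad = parent.grad + g


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad, out):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def backward(grad, out):
        moved = np.moveaxis(grad, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shifted = x - x.max_detached(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """Strided 3D convolution.

    x: (N, Cin, D, H, W); weight: (Cout, Cin, kd, kh, kw); bias: (Cout,).
    Implemented with an im2col forward and a scatter-add backward over
    kernel offsets; sizes in this package are desk-scale so this is fast.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    sd, sh, sw = stride
    pd, ph, pw = padding
    n, cin, d, h, w = x.shape
    cout, cin_w, kd, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, weight expects {cin_w}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    do = (d + 2 * pd - kd) // sd + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::sd, ::sh, ::sw]  # (N, Cin, do, ho, wo, kd, kh, kw)
    col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, cin * kd * kh * kw)
    wmat = weight.data.reshape(cout, -1)
    out = col @ wmat.T  # (N, P, Cout)
    if bias is not None:
        out = out + bias.data
    out_data = out.transpose(0, 2, 1).reshape(n, cout, do, ho, wo)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(grad, _out):
        gout = grad.reshape(n, cout, do * ho * wo).transpose(0, 2, 1)  # (N, P, Cout)
        gw = np.einsum("npo,npk->ok", gout, col).reshape(weight.shape)
        gb = gout.sum(axis=(0, 1)) if bias is not None else None
        gcol = gout @ wmat  # (N, P, Cin*k^3)
        gcol = gcol.reshape(n, do, ho, wo, cin, kd, kh, kw)
        gxp = np.zeros_like(xp)
        for a, b, c in itertools.product(range(kd), range(kh), range(kw)):
            gxp[:, :, a:a + sd * do:sd, b:b + sh * ho:sh, c:c + sw * wo:sw] += (
                gcol[:, :, :, :, :, a, b, c].transpose(0, 4, 1, 2, 3)
            )
        gx = gxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w]
        if bias is not None:
            return gx, gw, gb
        return gx, gw

    return Tensor._make(out_data, parents, backward)
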