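"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the models in this package: broadcasting
elementwise arithmetic, (batched) matmul, reshapes/transposes, reductions,
LeakyReLU, row softmax / log-softmax, 1-D unfolding for convolution, width-2
max pooling and dropout. Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` via topological traversal.

Float32 is the working precision of the models; the engine preserves
whatever dtype it is given so float64 oracle checks stay exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "unfold1d", "maxpool1d", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd core ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient on non-scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy() if node._backward is None else g
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        a, b = self, self._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor(a.data + b.data, parents=(a, b), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.data, parents=(a,), backward=lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g * b.data, a.shape)),
                    (b, _unbroadcast(g * a.data, b.shape)))

        return Tensor(a.data * b.data, parents=(a, b), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g / b.data, a.shape)),
                    (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape)))

        return Tensor(a.data / b.data, parents=(a, b), backward=bw)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            return ((a, g * e * a.data ** (e - 1.0)),)

        return Tensor(a.data ** e, parents=(a,), backward=bw)

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor(a.data @ b.data, parents=(a, b), backward=bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.shape
        return Tensor(a.data.reshape(*shape), parents=(a,),
                      backward=lambda g: ((a, g.reshape(old)),))

    def contiguous(self):
        a = self
        if a.data.flags["C_CONTIGUOUS"]:
            return a
        return Tensor(np.ascontiguousarray(a.data), parents=(a,),
                      backward=lambda g: ((a, g),))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor(np.swapaxes(a.data, ax1, ax2), parents=(a,),
                      backward=lambda g: ((a, np.swapaxes(g, ax1, ax2)),))

    def transpose(self, *axes):
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor(a.data.transpose(*axes), parents=(a,),
                      backward=lambda g: ((a, g.transpose(*inv)),))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.shape).copy()),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(gg, a.shape).copy()),)

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                      parents=(a,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------
    def leaky_relu(self, slope: float = 0.01):
        a = self
        dt = a.data.dtype.type
        mask = np.where(a.data > 0, dt(1.0), dt(slope))
        return Tensor(a.data * mask, parents=(a,),
                      backward=lambda g: ((a, g * mask),))

    def relu(self):
        return self.leaky_relu(0.0)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return ((a, y * (g - dot)),)

        return Tensor(y, parents=(a,), backward=bw)

    def log_softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        sm = np.exp(y)

        def bw(g):
            return ((a, g - sm * g.sum(axis=axis, keepdims=True)),)

        return Tensor(y, parents=(a,), backward=bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors),
                  backward=bw)


def unfold1d(x: Tensor, kernel: int, pad: int) -> Tensor:
    """(B, C, L) -> (B, C*kernel, L_out) sliding windows with zero padding.

    With pad = kernel // 2 (odd kernel) this is 'same' framing: L_out = L.
    """
    b, c, length = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    l_out = length + 2 * pad - kernel + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=-1)
    # (B, C, L_out, k) -> (B, C, k, L_out) -> (B, C*k, L_out)
    col = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
        b, c * kernel, l_out
    )

    def bw(g):
        gc = g.reshape(b, c, kernel, l_out)
        gxp = np.zeros_like(xp)
        for i in range(kernel):
            gxp[:, :, i : i + l_out] += gc[:, :, i, :]
        return ((x, gxp[:, :, pad : pad + length]),)

    return Tensor(col, parents=(x,), backward=bw)


def maxpool1d(x: Tensor, width: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (floor division)."""
    b, c, length = x.shape
    l_out = length // width
    if l_out < 1:
        raise ValueError(f"sequence of length {length} too short for pool {width}")
    trimmed = x.data[:, :, : l_out * width].reshape(b, c, l_out, width)
    arg = trimmed.argmax(axis=-1)
    y = np.take_along_axis(trimmed, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros((b, c, l_out, width), dtype=g.dtype)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        out = np.zeros_like(x.data)
        out[:, :, : l_out * width] = gx.reshape(b, c, l_out * width)
        return ((x, out),)

    return Tensor(y, parents=(x,), backward=bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(keep)
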