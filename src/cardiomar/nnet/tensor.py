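"""A small reverse-mode automatic differentiation engine on numpy arrays.

Sized for the compact encoder-decoder networks this package trains:
tensors wrap float32 ndarrays, gradients flow through a topologically
sorted tape, and the convolution primitives use an offset-slice im2col
so the inner loops are BLAS matrix products.  Layout convention is
``(N, C, *spatial)`` with 1-3 spatial dimensions.
"""

from __future__ import annotations

import itertools

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
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
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float32), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, slope))
        return out

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Convolution (1-3 spatial dims, odd kernels, 'same' padding)


def _offsets(kernel, stride, out_sp):
    for kidx in itertools.product(*(range(k) for k in kernel)):
        yield tuple(
            slice(ki, ki + o * stride, stride) for ki, o in zip(kidx, out_sp)
        )


def _im2col(xp: np.ndarray, kernel: tuple[int, ...], stride: int,
            out_sp: tuple[int, ...]) -> np.ndarray:
    """Gather kernel-offset slices: returns (N, C_in * K, out_vox)."""
    n, c = xp.shape[:2]
    k_total = int(np.prod(kernel))
    v = int(np.prod(out_sp))
    cols = np.empty((n, c, k_total, v), dtype=np.float32)
    for j, sl in enumerate(_offsets(kernel, stride, out_sp)):
        cols[:, :, j] = xp[(slice(None), slice(None)) + sl].reshape(n, c, v)
    return cols.reshape(n, c * k_total, v)


def _col2im(gcols: np.ndarray, xp_shape, kernel, stride, out_sp) -> np.ndarray:
    """Scatter-add the im2col gradient back to the padded input."""
    n, c = xp_shape[:2]
    k_total = int(np.prod(kernel))
    g = gcols.reshape(n, c, k_total, -1)
    gxp = np.zeros(xp_shape, dtype=np.float32)
    for j, sl in enumerate(_offsets(kernel, stride, out_sp)):
        gxp[(slice(None), slice(None)) + sl] += np.ascontiguousarray(
            g[:, :, j]
        ).reshape((n, c) + tuple(out_sp))
    return gxp


def conv_nd(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """N-dimensional convolution with 'same' zero padding for stride 1.

    ``w`` has shape ``(C_out, C_in, *kernel)`` with odd kernel sizes; for
    ``stride > 1`` the spatial size divides exactly by the stride.
    """
    kernel = w.shape[2:]
    spatial = x.shape[2:]
    pad = tuple(k // 2 for k in kernel)
    if stride == 1:
        out_sp = spatial
    else:
        out_sp = tuple(s // stride for s in spatial)
    pad_width = ((0, 0), (0, 0)) + tuple(
        (p, (o - 1) * stride + k - s - p)
        for p, k, s, o in zip(pad, kernel, spatial, out_sp)
    )
    xp = np.pad(x.data, pad_width)
    cols = _im2col(xp, kernel, stride, out_sp)  # (N, C_in*K, V)
    c_out = w.shape[0]
    wmat = w.data.reshape(c_out, -1)  # (C_out, C_in*K)
    n = x.shape[0]
    y = np.matmul(wmat, cols) + b.data.reshape(1, -1, 1)  # (N, C_out, V)
    out = Tensor(y.reshape((n, c_out) + tuple(out_sp)), parents=(x, w, b))

    def bw(g):
        gy = np.ascontiguousarray(g).reshape(n, c_out, -1)  # (N, C_out, V)
        b._accum(gy.sum(axis=(0, 2)))
        gw = np.einsum("ncv,nkv->ck", gy, cols, optimize=True)
        w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gy)  # (N, C_in*K, V)
            gxp = _col2im(gcols, xp.shape, kernel, stride, out_sp)
            core = tuple(
                slice(pw[0], dim - pw[1])
                for pw, dim in zip(pad_width[2:], xp.shape[2:])
            )
            x._accum(gxp[(slice(None), slice(None)) + core])

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Repeat each spatial voxel ``factor`` times along every spatial axis."""
    nd = x.data.ndim - 2
    y = x.data
    for ax in range(2, 2 + nd):
        y = np.repeat(y, factor, axis=ax)
    out = Tensor(y, parents=(x,))

    def bw(g):
        for ax in range(2, 2 + nd):
            shp = list(g.shape)
            shp[ax] //= factor
            shp.insert(ax + 1, factor)
            g = g.reshape(shp).sum(axis=ax + 1)
        x._accum(g)

    out._backward = bw
    return out
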