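"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  The op set is exactly what the cell-cycle
manifold networks need: broadcasting arithmetic, matmul, strided convolution
and transposed convolution (via zero-upsampling), batch normalisation,
common pointwise nonlinearities and stable log-softmax.

Everything runs in the dtype of the input arrays; float32 is used for
network training, float64 for the analytic loss checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---------------------------------------------------------------- infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for long sequences
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        # interior-node grads are per-backward-call scratch; only leaves
        # (parameters) accumulate across calls
        for node in topo:
            if node._backward is not None:
                node.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(self.data @ other.data, (self, other), bw)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def softplus(self):
        """log(1 + exp(x)), computed overflow-safely."""
        x = self.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-x))

        def bw(g):
            self._accum(g * sig)

        return self._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, self.data, slope * self.data), (self,), bw)

    def relu(self):
        return self.leaky_relu(0.0)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def log_softmax(self, axis: int = -1):
        """Numerically stable log-softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        softmax = np.exp(out_data)

        def bw(g):
            self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # ----------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    def flip(self, axis):
        def bw(g):
            self._accum(np.flip(g, axis))

        return self._make(np.flip(self.data, axis), (self,), bw)

    def pad2d(self, p: int):
        """Zero-pad the two trailing (spatial) axes by ``p`` on each side."""
        if p == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(p, p), (p, p)]

        def bw(g):
            sl = (Ellipsis, slice(p, -p), slice(p, -p))
            self._accum(g[sl])

        return self._make(np.pad(self.data, width), (self,), bw)

    def upsample_zeros(self, stride: int):
        """Insert ``stride - 1`` zeros between spatial samples (N, C, H, W)."""
        if stride == 1:
            return self
        n, c, h, w = self.shape
        out_data = np.zeros(
            (n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=self.dtype
        )
        out_data[:, :, ::stride, ::stride] = self.data

        def bw(g):
            self._accum(g[:, :, ::stride, ::stride])

        return self._make(out_data, (self,), bw)

    # -------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation.  ``self`` (N,C,H,W), ``weight`` (F,C,k,k)."""
        x = self.pad2d(padding)
        n, c, h, w = x.shape
        f, _, kh, kw = weight.shape
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(
            x.data, (kh, kw), axis=(2, 3)
        )[:, :, ::stride, ::stride]  # view: (N, C, oh, ow, kh, kw)
        out_data = np.einsum("nchwij,fcij->nfhw", windows, weight.data,
                             optimize=True)

        def bw(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nfhw,nchwij->fcij", g, windows,
                                        optimize=True))
            if x.requires_grad:
                gwin = np.einsum("nfhw,fcij->nchwij", g, weight.data,
                                 optimize=True)
                gx = np.zeros_like(x.data)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + oh * stride : stride,
                           j : j + ow * stride : stride] += gwin[:, :, :, :, i, j]
                x._accum(gx)

        out = self._make_conv(out_data, (x, weight), bw)
        if bias is not None:
            out = out + bias.reshape(1, f, 1, 1)
        return out

    def _make_conv(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0):
        """Transposed convolution (adjoint of conv2d w.r.t. its input).

        ``weight`` has layout (C_in, C_out, k, k); output spatial size is
        ``(H - 1) * stride - 2 * padding + k``.
        """
        x = self
        n, c, h, w = x.shape
        _, f, kh, kw = weight.shape
        s = stride
        fh, fw = (h - 1) * s + kh, (w - 1) * s + kw  # un-cropped extent
        oh, ow = fh - 2 * padding, fw - 2 * padding

        prod = np.einsum("nchw,cfij->nfhwij", x.data, weight.data,
                         optimize=True)
        full = np.zeros((n, f, fh, fw), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                full[:, :, i : i + h * s : s, j : j + w * s : s] += \
                    prod[:, :, :, :, i, j]
        p = padding
        out_data = full[:, :, p : p + oh, p : p + ow]

        def bw(g):
            gfull = np.zeros((n, f, fh, fw), dtype=g.dtype)
            gfull[:, :, p : p + oh, p : p + ow] = g
            gwin = np.lib.stride_tricks.sliding_window_view(
                gfull, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
            # gwin view: (N, F, h, w, kh, kw)
            if weight.requires_grad:
                weight._accum(np.einsum("nchw,nfhwij->cfij", x.data, gwin,
                                        optimize=True))
            if x.requires_grad:
                x._accum(np.einsum("nfhwij,cfij->nchw", gwin, weight.data,
                                   optimize=True))

        out = self._make_conv(out_data, (x, weight), bw)
        if bias is not None:
            out = out + bias.reshape(1, f, 1, 1)
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out
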