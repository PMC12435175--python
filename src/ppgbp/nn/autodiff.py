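"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the spirit of micrograd, but operating on
whole ``numpy`` arrays so that 1-D convolutional networks train at usable
speed on a CPU.  Only the operations needed by the regression
architectures are implemented: broadcast arithmetic, matmul, relu/exp/
tanh, reductions, shape ops, strided 1-D convolution, max pooling and a
causal long convolution (for the state-space layer).

Gradients are accumulated into ``Tensor.grad`` (a numpy array of the same
shape as ``data``) by :meth:`Tensor.backward`, which runs a topological
sort of the recorded graph.  All floating point work is float32 unless
the caller supplies float64 data.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "longconv_causal"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if not isinstance(data, np.ndarray):
            if isinstance(data, np.generic):
                data = np.asarray(data)  # keep numpy scalar dtype (e.g. float64 sums)
            else:
                data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = backward
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - val ** 2))

        out._backward = backward
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * val * (1 - val))

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = backward
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = backward
        return out

    def slice(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accum(full)

        out._backward = backward
        return out

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}

        # propagate using the per-node closures; closures accumulate into
        # parents' .grad, so route through a temporary holder
        self._accum(grads[id(self)])
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # intermediate (non-leaf) grads are left in place; callers that
        # care only about parameters read Parameter.grad


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = backward
    return out


# ----------------------------------------------------------------------
# convolution primitives
# ----------------------------------------------------------------------

def _im2col(x: np.ndarray, K: int, stride: int) -> np.ndarray:
    """(B, C, L) -> windows (B, C, Lout, K) as a strided view."""
    B, C, L = x.shape
    Lout = (L - K) // stride + 1
    sb, sc, sl = x.strides
    return as_strided(x, shape=(B, C, Lout, K), strides=(sb, sc, sl * stride, sl))


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D cross-correlation: x (B,Cin,L), w (Cout,Cin,K) -> (B,Cout,Lout)."""
    B, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lp = xp.shape[2]
    if Lp < K:
        raise ValueError(f"input length {L} (+2*{pad} pad) shorter than kernel {K}")
    windows = _im2col(xp, K, stride)                      # (B,Cin,Lout,K)
    Lout = windows.shape[2]
    cols = windows.transpose(0, 2, 1, 3).reshape(B * Lout, Cin * K)
    W2 = w.data.reshape(Cout, Cin * K)
    y = (cols @ W2.T).reshape(B, Lout, Cout).transpose(0, 2, 1)
    if b is not None:
        y = y + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), _parents=parents)

    def backward(g):
        # g: (B, Cout, Lout)
        G2 = g.transpose(0, 2, 1).reshape(B * Lout, Cout)
        if w.requires_grad:
            gw = (G2.T @ cols).reshape(Cout, Cin, K)
            w._accum(gw.astype(w.data.dtype, copy=False))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)).astype(b.data.dtype, copy=False))
        if x.requires_grad:
            # grad wrt padded input: scatter G2 @ W2 back into windows
            gcols = (G2 @ W2).reshape(B, Lout, Cin, K).transpose(0, 2, 1, 3)
            gxp = np.zeros((B, Cin, Lp), dtype=x.data.dtype)
            # accumulate window gradients; loop over kernel taps (K is small)
            for k in range(K):
                gxp[:, :, k:k + Lout * stride:stride] += gcols[:, :, :, k]
            gx = gxp[:, :, pad:Lp - pad] if pad else gxp
            x._accum(gx)

    out._backward = backward
    return out


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling with kernel == stride == k."""
    B, C, L = x.data.shape
    Lout = L // k
    trimmed = x.data[:, :, : Lout * k].reshape(B, C, Lout, k)
    arg = trimmed.argmax(axis=3)
    out = Tensor(np.ascontiguousarray(trimmed.max(axis=3)), _parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((B, C, Lout, k), dtype=x.data.dtype)
        bi, ci, li = np.ogrid[:B, :C, :Lout]
        gx[bi, ci, li, arg] = g
        full = np.zeros_like(x.data)
        full[:, :, : Lout * k] = gx.reshape(B, C, Lout * k)
        x._accum(full)

    out._backward = backward
    return out


def longconv_causal(x: Tensor, kern: Tensor) -> Tensor:
    """Depthwise causal convolution with a long kernel (FFT-based).

    x: (B, C, L), kern: (C, K).  Output y[b,c,t] = sum_{s<=t} k[c,t-s] x[b,c,s].
    """
    from scipy.signal import fftconvolve

    B, C, L = x.data.shape
    K = kern.data.shape[1]
    full = fftconvolve(x.data, kern.data[None, :, :], axes=2)
    out = Tensor(np.ascontiguousarray(full[:, :, :L]).astype(x.data.dtype, copy=False),
                 _parents=(x, kern))

    def backward(g):
        # pad g to full-conv length so correlations line up
        if kern.requires_grad:
            # gk[c,t] = sum_{b,s} x[b,c,s] g[b,c,s+t]
            corr = fftconvolve(g, x.data[:, :, ::-1], axes=2)  # index L-1+t holds the sum
            gk = corr[:, :, L - 1: L - 1 + K].sum(axis=0)
            kern._accum(gk.astype(kern.data.dtype, copy=False))
        if x.requires_grad:
            # gx[b,c,s] = sum_{t>=s} k[c,t-s] g[b,c,t]  (correlation with kernel)
            corr = fftconvolve(g, kern.data[None, :, ::-1], axes=2)
            gx = corr[:, :, K - 1: K - 1 + L]
            x._accum(gx.astype(x.data.dtype, copy=False))

    out._backward = backward
    return out
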