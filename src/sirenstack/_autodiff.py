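"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's networks need: dense affine
layers with sine/ReLU nonlinearities, 2-D convolution with 'same' padding,
2x2 max pooling, nearest-neighbour 2x upsampling, channel concatenation and
mean-squared-error reduction.  Everything runs in float32.

The Adam and SGD optimizers operate on lists of parameter tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Adam", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ ops
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data - other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def sin(self) -> "Tensor":
        out = Tensor(np.sin(self.data), parents=(self,))

        def backward(g):
            self._accum(g * np.cos(self.data))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward(g):
            self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def mse_to(self, target: np.ndarray) -> "Tensor":
        """Mean squared error against a constant target; scalar output."""
        diff = self.data - np.asarray(target, dtype=np.float32)
        out = Tensor(np.mean(diff * diff), parents=(self,))

        def backward(g):
            self._accum(g * (2.0 / diff.size) * diff)

        out._backward = backward
        return out

    # --------------------------------------------------------- conv-net ops
    def conv2d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """'same'-padded 2-D convolution.

        self: (N, C, H, W); weight: (F, C, kh, kw) with odd kh, kw;
        bias: (F,).  Output (N, F, H, W).
        """
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        f, _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
        out_data = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,F)
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        out_data += bias.data[None, :, None, None]
        out = Tensor(out_data, parents=(self, weight, bias))

        def backward(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(dw)
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        # g: (N,F,H,W) x w[:,:,i,j]: (F,C) -> (N,C,H,W)
                        dxp[:, :, i:i + h, j:j + wd] += np.tensordot(
                            g, w[:, :, i, j], axes=([1], [0])
                        ).transpose(0, 3, 1, 2)
                self._accum(dxp[:, :, ph:ph + h, pw:pw + wd])

        out._backward = backward
        return out

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling with stride 2; H and W must be even."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dims")
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                     parents=(self,))

        def backward(g):
            dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(dxr.reshape(n, c, h, w))

        out._backward = backward
        return out

    def upsample2(self) -> "Tensor":
        """Nearest-neighbour 2x upsampling."""
        out = Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3), parents=(self,))

        def backward(g):
            n, c, h2, w2 = g.shape
            self._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

        out._backward = backward
        return out

    def concat_channels(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.concatenate([self.data, other.data], axis=1),
                     parents=(self, other))
        c0 = self.data.shape[1]

        def backward(g):
            if self.requires_grad:
                self._accum(g[:, :c0])
            if other.requires_grad:
                other._accum(g[:, c0:])

        out._backward = backward
        return out

    # ----------------------------------------------------------- backward
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones((), dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params, lr=0.01):
        self.params = list(params)
        self.lr = float(lr)

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= (self.lr * p.grad).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
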