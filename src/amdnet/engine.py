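"""A compact NumPy neural-network engine executing declarative block specs.

The engine compiles a :class:`~amdnet.specs.BlockSpec` tree into layer objects
with explicit forward and backward passes, so the same declarative description
drives both the analytic parameter audit and an executable, trainable model.
Keeping the runtime in NumPy makes every trainable scalar inspectable: the
framework-reported parameter count is literally the sum of array sizes, which
the audit cross-checks against the closed-form arithmetic.

Convolutions are evaluated as "shift-and-matmul": a k x k convolution is the
sum over the k^2 kernel taps of a (F x C) @ (C x N*H*W) matrix product on the
correspondingly shifted input.  This keeps the arithmetic inside BLAS without
materializing an im2col buffer, and the backward pass reuses the same shifted
views.  Depthwise convolutions are per-channel tap accumulations; max pooling
routes gradients to the per-window argmax.

Layout is NCHW throughout; default dtype is float32.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import erf

from .specs import BlockSpec, ConvSpec, InvalidSpecError, TensorShape, propagate_shape

__all__ = ["Model", "compile_model", "Adam", "softmax_cross_entropy"]


def _tune_allocator() -> None:
    # Layer outputs and temporaries are large arrays allocated and freed on
    # every pass.  glibc serves them via mmap and returns them to the kernel
    # on free, so each reallocation pays first-touch page faults.  Raising the
    # mmap threshold keeps these buffers in the malloc arena with warm pages.
    import ctypes
    import sys

    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except (OSError, AttributeError):
        pass


_tune_allocator()

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _out_size(size: int, k: int, stride: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(size / stride)
    return (size - k) // stride + 1


def _pad_amount(size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


class Layer:
    """Base class: forward caches what backward needs when training=True."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Standard convolution; also covers pointwise (k=1) and patch embedding.

    1x1/stride-1 kernels run as a batched (F x C) @ (C x H*W) matmul directly
    on the activation tensor; spatial kernels go through an im2col buffer
    filled by k^2 strided copies, chunked over the batch so the buffer stays
    below ~256 MB.
    """

    _CHUNK_ELEMS = 64_000_000  # float32 col-buffer cap per chunk

    def __init__(self, in_ch, filters, kernel, stride, padding, bias, rng, dtype, gain=2.0):
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        std = math.sqrt(gain / fan_in)
        self.w = rng.normal(0.0, std, size=(filters, in_ch, kh, kw)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self._cache = None

    @property
    def _pointwise(self) -> bool:
        return self.kernel == (1, 1) and self.stride == 1

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        f = self.w.shape[0]
        if self._pointwise:
            x3 = x.reshape(n, c, h * w)
            y = np.matmul(self.w.reshape(f, c)[None], x3).reshape(n, f, h, w)
            if self.b is not None:
                y += self.b[None, :, None, None]
            if training:
                self._cache = (x, None)
            return y
        kh, kw = self.kernel
        s = self.stride
        ho = _out_size(h, kh, s, self.padding)
        wo = _out_size(w, kw, s, self.padding)
        pt, pb = _pad_amount(h, kh, s, self.padding)
        pl, pr = _pad_amount(w, kw, s, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if pt + pb + pl + pr else x
        w2 = self.w.reshape(f, c * kh * kw)
        chunk = max(1, self._CHUNK_ELEMS // (c * kh * kw * ho * wo))
        y = np.empty((n, f, ho, wo), dtype=x.dtype)
        cols = [] if training else None
        for i in range(0, n, chunk):
            col = self._im2col(xp[i : i + chunk], ho, wo)
            if training:
                cols.append(col)
            yi = np.matmul(w2[None], col.reshape(col.shape[0], c * kh * kw, ho * wo))
            y[i : i + chunk] = yi.reshape(-1, f, ho, wo)
        if self.b is not None:
            y += self.b[None, :, None, None]
        if training:
            self._cache = (xp, (x.shape, (pt, pl), (ho, wo), chunk, cols))
        return y

    def _im2col(self, xp, ho, wo):
        """(n, C, kh*kw, Ho, Wo) patch buffer from a padded chunk."""
        n, c = xp.shape[:2]
        kh, kw = self.kernel
        s = self.stride
        col = np.empty((n, c, kh * kw, ho, wo), dtype=xp.dtype)
        for a in range(kh):
            for b in range(kw):
                col[:, :, a * kw + b] = xp[
                    :, :, a : a + (ho - 1) * s + 1 : s, b : b + (wo - 1) * s + 1 : s
                ]
        return col

    def backward(self, dy):
        cached, meta = self._cache
        self._cache = None
        f = self.w.shape[0]
        if self.b is not None:
            self.db = dy.sum(axis=(0, 2, 3))
        if self._pointwise:
            x = cached
            n, c, h, w = x.shape
            dy3 = np.ascontiguousarray(dy).reshape(n, f, h * w)
            x3 = x.reshape(n, c, h * w)
            w2 = self.w.reshape(f, c)
            # batched GEMM with implicit transpose; summed over the batch
            self.dw = np.matmul(dy3, x3.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.shape)
            dx = np.matmul(w2.T[None], dy3).reshape(n, c, h, w)
            return dx
        xp = cached
        xshape, (pt, pl), (ho, wo), chunk, cols = meta
        n, c, h, w = xshape
        kh, kw = self.kernel
        s = self.stride
        w2 = self.w.reshape(f, c * kh * kw)
        dw2 = np.zeros_like(w2)
        dxp = np.zeros_like(xp)
        dy = np.ascontiguousarray(dy)
        for ci, i in enumerate(range(0, n, chunk)):
            dyi = dy[i : i + chunk].reshape(-1, f, ho * wo)
            col = cols[ci]
            col3 = col.reshape(col.shape[0], c * kh * kw, ho * wo)
            dw2 += np.matmul(dyi, col3.transpose(0, 2, 1)).sum(axis=0)
            dcol = np.matmul(w2.T[None], dyi).reshape(col.shape)
            for a in range(kh):
                for b in range(kw):
                    dxp[
                        i : i + chunk, :,
                        a : a + (ho - 1) * s + 1 : s, b : b + (wo - 1) * s + 1 : s,
                    ] += dcol[:, :, a * kw + b]
        self.dw = dw2.reshape(self.w.shape)
        return dxp[:, :, pt : pt + h, pl : pl + w]

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def grads(self):
        return [self.dw] if self.b is None else [self.dw, self.db]


@njit(cache=True, fastmath=True)
def _dw_conv(xp, w, y):  # pragma: no cover - exercised through DepthwiseConv2D
    """y[n,c,i,j] = sum_ab w[c,a,b] * xp[n,c,i+a,j+b]; xp pre-padded."""
    n_img, c_ch, _, _ = xp.shape
    kh, kw = w.shape[1], w.shape[2]
    h, wd = y.shape[2], y.shape[3]
    row = np.empty(wd, dtype=y.dtype)
    for n in range(n_img):
        for c in range(c_ch):
            for i in range(h):
                row[:] = 0.0
                for a in range(kh):
                    for b in range(kw):
                        wv = w[c, a, b]
                        for j in range(wd):
                            row[j] += wv * xp[n, c, i + a, j + b]
                for j in range(wd):
                    y[n, c, i, j] = row[j]


@njit(cache=True, fastmath=True)
def _dw_weight_grad(xp, dy, dw):  # pragma: no cover - exercised via backward
    """dw[c,a,b] = sum_nij dy[n,c,i,j] * xp[n,c,i+a,j+b]."""
    n_img, c_ch, _, _ = xp.shape
    kh, kw = dw.shape[1], dw.shape[2]
    h, wd = dy.shape[2], dy.shape[3]
    for n in range(n_img):
        for c in range(c_ch):
            for a in range(kh):
                for b in range(kw):
                    acc = 0.0
                    for i in range(h):
                        for j in range(wd):
                            acc += dy[n, c, i, j] * xp[n, c, i + a, j + b]
                    dw[c, a, b] += acc


class DepthwiseConv2D(Layer):
    """Per-channel spatial convolution (stride 1, 'same' padding).

    The tap loops are JIT-compiled; the input gradient is the 'same'-padded
    correlation of the upstream gradient with the spatially flipped kernel.
    """

    def __init__(self, in_ch, kernel, bias, rng, dtype, gain=2.0):
        kh, kw = kernel
        std = math.sqrt(gain / (kh * kw))
        self.w = rng.normal(0.0, std, size=(in_ch, kh, kw)).astype(dtype)
        self.b = np.zeros(in_ch, dtype=dtype) if bias else None
        self.kernel = kernel
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        kh, kw = self.kernel
        pt, pb = _pad_amount(h, kh, 1, "same")
        pl, pr = _pad_amount(w, kw, 1, "same")
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        y = np.empty_like(x)
        _dw_conv(xp, self.w, y)
        if self.b is not None:
            y += self.b[None, :, None, None]
        if training:
            self._cache = xp
        return y

    def backward(self, dy):
        xp = self._cache
        self._cache = None
        kh, kw = self.kernel
        h, w = dy.shape[2], dy.shape[3]
        pt, _ = _pad_amount(h, kh, 1, "same")
        pl, _ = _pad_amount(w, kw, 1, "same")
        self.dw = np.zeros_like(self.w)
        _dw_weight_grad(xp, np.ascontiguousarray(dy), self.dw)
        if self.b is not None:
            self.db = dy.sum(axis=(0, 2, 3))
        # dx = same-padded correlation of dy with the flipped kernel (odd k:
        # the flipped-kernel correlation reuses the forward padding offsets)
        dyp = np.pad(dy, ((0, 0), (0, 0), (kh - 1 - pt, pt), (kw - 1 - pl, pl)))
        wflip = np.ascontiguousarray(self.w[:, ::-1, ::-1])
        dx = np.empty((dy.shape[0], dy.shape[1], h, w), dtype=dy.dtype)
        _dw_conv(dyp, wflip, dx)
        return dx

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def grads(self):
        return [self.dw] if self.b is None else [self.dw, self.db]


class MaxPool2D(Layer):
    """Max pooling; gradients route to the first position attaining the max."""

    def __init__(self, kernel, stride, padding="same"):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def _taps(self, xp, ho, wo):
        kh, kw = self.kernel
        s = self.stride
        for a in range(kh):
            for b in range(kw):
                yield a, b, xp[:, :, a : a + (ho - 1) * s + 1 : s, b : b + (wo - 1) * s + 1 : s]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        kh, kw = self.kernel
        s = self.stride
        ho = _out_size(h, kh, s, self.padding)
        wo = _out_size(w, kw, s, self.padding)
        pt, pb = _pad_amount(h, kh, s, self.padding)
        pl, pr = _pad_amount(w, kw, s, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
        y = None
        for _, _, tap in self._taps(xp, ho, wo):
            y = tap.copy() if y is None else np.maximum(y, tap, out=y)
        if training:
            self._cache = (xp, y, (pt, pl), x.shape, (ho, wo))
        return y

    def backward(self, dy):
        xp, y, (pt, pl), xshape, (ho, wo) = self._cache
        self._cache = None
        n, c, h, w = xshape
        s = self.stride
        dxp = np.zeros_like(xp, dtype=dy.dtype)
        used = np.zeros(y.shape, dtype=bool)
        for a, b, tap in self._taps(xp, ho, wo):
            hit = (tap == y) & ~used
            used |= hit
            dxp[:, :, a : a + (ho - 1) * s + 1 : s, b : b + (wo - 1) * s + 1 : s] += dy * hit
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2D(Layer):
    """Channel-wise batch normalization with trainable scale and shift."""

    def __init__(self, channels, dtype, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, training=False):
        if training:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            s1 = x.sum(axis=(0, 2, 3), dtype=np.float64)
            s2 = np.einsum("nchw,nchw->c", x, x, dtype=np.float64)
            mean = (s1 / m).astype(x.dtype)
            var = np.maximum(s2 / m - (s1 / m) ** 2, 0.0).astype(x.dtype)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma = np.einsum("nchw,nchw->c", dy, xhat)
        self.dbeta = dy.sum(axis=(0, 2, 3))
        g = (self.gamma * inv_std)[None, :, None, None]
        dx = g * (
            dy
            - (self.dbeta / m)[None, :, None, None]
            - xhat * (self.dgamma / m)[None, :, None, None]
        )
        return dx

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Dense(Layer):
    def __init__(self, in_features, units, bias, rng, dtype, gain=2.0):
        std = math.sqrt(gain / in_features)
        self.w = rng.normal(0.0, std, size=(in_features, units)).astype(dtype)
        self.b = np.zeros(units, dtype=dtype) if bias else None
        self._cache = None

    def forward(self, x, training=False):
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        if training:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        self._cache = None
        self.dw = x.T @ dy
        if self.b is not None:
            self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def grads(self):
        return [self.dw] if self.b is None else [self.dw, self.db]


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / self._hw


class Activation(Layer):
    """Elementwise nonlinearity.

    The softmax variant only ever terminates the network in front of a
    cross-entropy loss; its backward therefore expects the gradient already
    expressed at the logits (the trainer passes ``(p - onehot)/N``) and passes
    it through unchanged.
    """

    def __init__(self, kind):
        self.kind = kind
        self._cache = None

    def forward(self, x, training=False):
        if self.kind == "relu":
            # safe in place: a leaf's activation always follows a fresh
            # conv/BN/dense output that no other layer holds
            y = np.maximum(x, 0.0, out=x)
            if training:
                self._cache = y
        elif self.kind == "gelu":
            y = 0.5 * x * (1.0 + erf(x * _INV_SQRT2))
            if training:
                self._cache = x
        elif self.kind == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-x))
            if training:
                self._cache = y
        elif self.kind == "softmax":
            z = x - x.max(axis=-1, keepdims=True)
            e = np.exp(z)
            y = e / e.sum(axis=-1, keepdims=True)
        else:  # pragma: no cover
            raise InvalidSpecError(self.kind)
        return y

    def backward(self, dy):
        if self.kind == "relu":
            y = self._cache
            self._cache = None
            return dy * (y > 0)
        if self.kind == "gelu":
            x = self._cache
            self._cache = None
            cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
            pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
            return dy * (cdf + x * pdf)
        if self.kind == "sigmoid":
            y = self._cache
            self._cache = None
            return dy * y * (1.0 - y)
        # softmax: cross-entropy shortcut (see class docstring)
        return dy


class Leaf(Layer):
    """A compiled ConvSpec: main layer + optional batch norm + activation."""

    def __init__(self, spec: ConvSpec, in_channels: int, input_name: str, sublayers):
        self.spec = spec
        self.in_channels = in_channels
        self.input_name = input_name
        self.sublayers = sublayers

    def forward(self, x, training=False):
        for layer in self.sublayers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.sublayers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.sublayers for p in layer.params()]

    def grads(self):
        return [g for layer in self.sublayers for g in layer.grads()]


class Sequential(Layer):
    def __init__(self, name, children):
        self.name = name
        self.children = children

    def forward(self, x, training=False):
        for child in self.children:
            x = child.forward(x, training=training)
        return x

    def backward(self, dy):
        for child in reversed(self.children):
            dy = child.backward(dy)
        return dy

    def params(self):
        return [p for c in self.children for p in c.params()]

    def grads(self):
        return [g for c in self.children for g in c.grads()]


class ParallelConcat(Layer):
    def __init__(self, name, branches):
        self.name = name
        self.branches = branches
        self._splits = None

    def forward(self, x, training=False):
        outs = [b.forward(x, training=training) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dx = None
        for branch, part in zip(self.branches, parts):
            d = branch.backward(np.ascontiguousarray(part))
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def grads(self):
        return [g for b in self.branches for g in b.grads()]


class Residual(Layer):
    def __init__(self, name, inner):
        self.name = name
        self.inner = inner

    def forward(self, x, training=False):
        return x + self.inner.forward(x, training=training)

    def backward(self, dy):
        return dy + self.inner.backward(dy)

    def params(self):
        return self.inner.params()

    def grads(self):
        return self.inner.grads()


class ScaleBlock(Layer):
    """Channel attention: output = input * weights(input), weights in (0,1)."""

    def __init__(self, name, inner):
        self.name = name
        self.inner = inner
        self._cache = None

    def forward(self, x, training=False):
        w = self.inner.forward(x, training=training)
        if training:
            self._cache = (x, w)
        return x * w[:, :, None, None]

    def backward(self, dy):
        x, w = self._cache
        self._cache = None
        dw = np.einsum("nchw,nchw->nc", dy, x)
        dx = dy * w[:, :, None, None]
        return dx + self.inner.backward(dw)

    def params(self):
        return self.inner.params()

    def grads(self):
        return self.inner.grads()


# ---------------------------------------------------------------------------
# compilation


def _compile_leaf(spec: ConvSpec, in_shape: TensorShape, input_name, rng, dtype) -> Leaf:
    c = in_shape.channels
    gain = 1.0 if spec.activation in ("sigmoid", "softmax", "none") else 2.0
    sub: list[Layer] = []
    if spec.kind in ("standard", "pointwise"):
        sub.append(Conv2D(c, spec.filters, spec.kernel, spec.stride, spec.padding,
                          spec.bias, rng, dtype, gain))
    elif spec.kind == "depthwise":
        sub.append(DepthwiseConv2D(c, spec.kernel, spec.bias, rng, dtype, gain))
    elif spec.kind == "maxpool":
        sub.append(MaxPool2D(spec.kernel, spec.stride, spec.padding))
    elif spec.kind == "dense":
        sub.append(Dense(c, spec.filters, spec.bias, rng, dtype, gain))
    elif spec.kind == "gap":
        sub.append(GlobalAvgPool())
    if spec.batchnorm:
        out_c = propagate_shape(spec, in_shape).channels
        sub.append(BatchNorm2D(out_c, dtype))
    if spec.activation != "none":
        sub.append(Activation(spec.activation))
    return Leaf(spec, c, input_name, sub)


def _compile(node, in_shape, input_name, rng, dtype):
    if isinstance(node, ConvSpec):
        return _compile_leaf(node, in_shape, input_name, rng, dtype)
    if node.topology == "sequential":
        children, shape, prev = [], in_shape, input_name
        for child in node.nodes:
            children.append(_compile(child, shape, prev, rng, dtype))
            shape = propagate_shape(child, shape)
            prev = child.name
        return Sequential(node.name, children)
    if node.topology == "parallel_concat":
        return ParallelConcat(
            node.name, [_compile(c, in_shape, input_name, rng, dtype) for c in node.nodes]
        )
    if node.topology == "residual":
        inner = BlockSpec(name=node.name + "_inner", topology="sequential", nodes=node.nodes)
        return Residual(node.name, _compile(inner, in_shape, input_name, rng, dtype))
    inner = BlockSpec(name=node.name + "_inner", topology="sequential", nodes=node.nodes)
    return ScaleBlock(node.name, _compile(inner, in_shape, input_name, rng, dtype))


class Model:
    """A compiled, executable network with NCHW float inputs."""

    def __init__(self, root: Layer, spec, in_shape: TensorShape, dtype):
        self.root = root
        self.spec = spec
        self.in_shape = in_shape
        self.dtype = dtype

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        return self.root.forward(x, training=training)

    predict_proba = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return np.argmax(self.forward(x), axis=1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.root.backward(np.asarray(dlogits, dtype=self.dtype))

    def params(self) -> list[np.ndarray]:
        return self.root.params()

    def grads(self) -> list[np.ndarray]:
        return self.root.grads()

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params()))

    def _state_arrays(self) -> list[np.ndarray]:
        """Trainable parameters plus BN running statistics, in stable order.

        Checkpoints must capture the running statistics: restoring trainable
        weights against statistics accumulated later would not reproduce the
        checkpointed model's evaluation behaviour.
        """
        arrays = list(self.params())
        for leaf in self.leaves():
            for sub in leaf.sublayers:
                if isinstance(sub, BatchNorm2D):
                    arrays.extend([sub.running_mean, sub.running_var])
        return arrays

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._state_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self._state_arrays()
        if len(own) != len(weights):
            raise ValueError("weight list does not match model state")
        for p, w in zip(own, weights):
            p[...] = w

    def leaves(self) -> list[Leaf]:
        found: list[Leaf] = []

        def walk(layer):
            if isinstance(layer, Leaf):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for c in layer.children:
                    walk(c)
            elif isinstance(layer, ParallelConcat):
                for b in layer.branches:
                    walk(b)
            elif isinstance(layer, (Residual, ScaleBlock)):
                walk(layer.inner)

        walk(self.root)
        return found


def compile_model(
    spec: BlockSpec,
    in_shape: TensorShape,
    seed: int = 0,
    dtype=np.float32,
    input_name: str = "Input_Image",
) -> Model:
    """Instantiate weights for a block spec and return an executable model."""
    propagate_shape(spec, in_shape)  # validate before allocating
    rng = np.random.default_rng(seed)
    root = _compile(spec, in_shape, input_name, rng, dtype)
    return Model(root, spec, in_shape, dtype)


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax_cross_entropy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits.

    ``probs`` are softmax outputs, ``labels`` integer class indices.  The
    returned gradient ``(p - onehot)/N`` is fed to ``Model.backward`` (the
    terminal softmax activation passes it through; see :class:`Activation`).
    """
    n = probs.shape[0]
    p_true = np.clip(probs[np.arange(n), labels], 1e-12, None)
    loss = float(-np.log(p_true).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a fixed parameter list; ``lr`` is mutable."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self._v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self._params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g, dtype=np.float64)
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
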