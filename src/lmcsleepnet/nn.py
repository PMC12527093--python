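"""Minimal NumPy neural-network engine with reverse-mode gradients.

Layers are stateful modules: ``forward`` caches what ``backward`` needs, and
``backward`` consumes the cache of the most recent forward call (one in-flight
activation per module, which is all a feed-forward classifier needs).  All
floating-point state is float32.

Convolutions are evaluated by extracting kernel-tap patches with strided
slicing (one slice per tap, so a 3x3 kernel costs nine vectorised copies) and
contracting them with BLAS matmul/einsum; gradients scatter back through the
same tap slices.  This keeps both passes vectorised without any per-pixel
Python loops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Dropout",
    "Flatten",
    "Linear",
    "softmax",
]


class Parameter:
    """A trainable tensor.

    ``decay`` marks whether the optimizer applies L2 weight decay to it
    (convolution/linear weights yes; norm affine parameters and biases no).
    """

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.decay = decay

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- introspection -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{prefix}{name}.{i}.")

    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            for attr in ("running_mean", "running_var"):
                if hasattr(m, attr):
                    state[f"{name}.{attr}"] = getattr(m, attr).copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, m in self.named_modules():
            for attr in ("running_mean", "running_var"):
                key = f"{name}.{attr}"
                if hasattr(m, attr) and key in state:
                    getattr(m, attr)[...] = state[key]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# patch extraction helpers
# ---------------------------------------------------------------------------

def conv_output_size(size: int, k: int, stride: int, pad: int, dilation: int = 1) -> int:
    return (size + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def _extract_patches(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
                     dilation: int, pad_value: float = 0.0) -> np.ndarray:
    """[N,C,H,W] -> [N,C,kh,kw,Ho,Wo] kernel-tap view (copied, contiguous)."""
    n, c, h, w = x.shape
    ho = conv_output_size(h, kh, stride, pad, dilation)
    wo = conv_output_size(w, kw, stride, pad, dilation)
    if pad > 0:
        xp = np.full((n, c, h + 2 * pad, w + 2 * pad), pad_value, dtype=x.dtype)
        xp[:, :, pad:pad + h, pad:pad + w] = x
    else:
        xp = x
    out = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i, j] = xp[:, :, i * dilation:i * dilation + stride * ho:stride,
                                 j * dilation:j * dilation + stride * wo:stride]
    return out


def _scatter_patches(dpatches: np.ndarray, x_shape, kh: int, kw: int,
                     stride: int, pad: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`_extract_patches`: accumulate tap gradients into dx."""
    n, c, h, w = x_shape
    _, _, _, _, ho, wo = dpatches.shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dpatches.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i * dilation:i * dilation + stride * ho:stride,
                j * dilation:j * dilation + stride * wo:stride] += dpatches[:, :, i, j]
    if pad > 0:
        return dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Dense 2-D convolution (cross-correlation), optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), decay=False) if bias else None
        self._cache = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        k, s, p, d = self.kernel_size, self.stride, self.padding, self.dilation
        patches = _extract_patches(x, k, k, s, p, d)
        n, c, _, _, ho, wo = patches.shape
        cols = patches.reshape(n, c * k * k, ho * wo)
        w2 = self.weight.data.reshape(self.out_channels, c * k * k)
        out = np.matmul(w2, cols).reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x.shape, cols, ho, wo)
        return out

    def backward(self, dout):
        x_shape, cols, ho, wo = self._cache
        n = x_shape[0]
        k, s, p, d = self.kernel_size, self.stride, self.padding, self.dilation
        dout2 = dout.reshape(n, self.out_channels, ho * wo)
        # dW = sum_n dout2 @ cols^T
        dw = np.einsum("nol,ncl->oc", dout2, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dout2.sum(axis=(0, 2))
        w2 = self.weight.data.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, dout2)  # [N, C*k*k, L]
        dpatches = dcols.reshape(n, x_shape[1], k, k, ho, wo)
        return _scatter_patches(dpatches, x_shape, k, k, s, p, d)


class DepthwiseConv2d(Module):
    """Per-channel 3x3 (or kxk) spatial filtering; no channel mixing."""

    def __init__(self, channels: int, kernel_size: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(
            _he_normal(rng, (channels, kernel_size, kernel_size), fan_in))
        self._cache = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        k, s, p = self.kernel_size, self.stride, self.padding
        patches = _extract_patches(x, k, k, s, p, 1)  # [N,C,k,k,Ho,Wo]
        n, c, _, _, ho, wo = patches.shape
        pk = patches.reshape(n, c, k * k, ho * wo)
        wk = self.weight.data.reshape(c, k * k)
        out = np.einsum("nckl,ck->ncl", pk, wk, optimize=True).reshape(n, c, ho, wo)
        self._cache = (x.shape, pk, ho, wo)
        return out

    def backward(self, dout):
        x_shape, pk, ho, wo = self._cache
        n, c = x_shape[0], x_shape[1]
        k, s, p = self.kernel_size, self.stride, self.padding
        dout2 = dout.reshape(n, c, ho * wo)
        dw = np.einsum("nckl,ncl->ck", pk, dout2, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        wk = self.weight.data.reshape(c, k * k)
        dpk = np.einsum("ncl,ck->nckl", dout2, wk, optimize=True)
        dpatches = dpk.reshape(n, c, k, k, ho, wo)
        return _scatter_patches(dpatches, x_shape, k, k, s, p, 1)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32), decay=False)
        self.bias = Parameter(np.zeros(channels, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = xhat * self.weight.data[None, :, None, None] + self.bias.data[None, :, None, None]
        self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv_std = self._cache
        self.weight.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        if not self.training:
            return dout * (self.weight.data * inv_std)[None, :, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * self.weight.data[None, :, None, None]
        # standard batch-norm gradient w.r.t. the mini-batch statistics
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        del n
        return ((term1 - term2 - term3) * inv_std[None, :, None, None]).astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Sigmoid(Module):
    def forward(self, x):
        out = sigmoid(x)
        self._out = out
        return out

    def backward(self, dout):
        return (dout * self._out * (1.0 - self._out)).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x):
        k, s, p = self.kernel_size, self.stride, self.padding
        patches = _extract_patches(x, k, k, s, p, 1, pad_value=-np.inf)
        n, c, _, _, ho, wo = patches.shape
        pk = patches.reshape(n, c, k * k, ho, wo)
        idx = pk.argmax(axis=2)
        out = np.take_along_axis(pk, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (x.shape, idx, ho, wo)
        return out

    def backward(self, dout):
        x_shape, idx, ho, wo = self._cache
        n, c = x_shape[0], x_shape[1]
        k, s, p = self.kernel_size, self.stride, self.padding
        dpk = np.zeros((n, c, k * k, ho, wo), dtype=dout.dtype)
        np.put_along_axis(dpk, idx[:, :, None], dout[:, :, None], axis=2)
        dpatches = dpk.reshape(n, c, k, k, ho, wo)
        return _scatter_patches(dpatches, x_shape, k, k, s, p, 1)


class GlobalAvgPool2d(Module):
    """Adaptive average pool to 1x1, returned flattened to [N, C]."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dropout(Module):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), decay=False) if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out.astype(np.float32)

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return (dout @ self.weight.data).astype(np.float32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
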