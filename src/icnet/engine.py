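"""Minimal numpy neural-network engine.

Layers operate on rank-4 feature maps ordered ``(batch, height, width,
channels)`` and implement explicit ``forward``/``backward`` passes with
per-layer caches, so the whole segmentation network can be trained on a
CPU with nothing beyond numpy. Parameters are held in :class:`Parameter`
objects that the Adam optimizer updates in place.

Only the operations the architecture needs are provided: stride-1 "same"
or "valid" 2-D convolution (im2col), 2x2/stride-2 max pooling and
transpose convolution, batch normalization with learnable scale/shift,
and the elementwise activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2D",
    "ConvTranspose2x2",
    "BatchNorm",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "MaxPool2x2",
    "Adam",
    "softmax",
    "he_uniform",
]


class Parameter:
    """A named tensor with a gradient slot.

    ``trainable=False`` marks buffers such as batch-norm running
    statistics, which are counted separately and never touched by the
    optimizer.
    """

    def __init__(self, value: np.ndarray, name: str, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.value.shape}, trainable={self.trainable})"


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Variance-scaling uniform initialization, limit sqrt(6 / fan_in)."""
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: layers expose parameters and forward/backward."""

    def parameters(self) -> list:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _im2col(x: np.ndarray, fh: int, fw: int):
    """View the padded input as patch columns, shape (B*oh*ow, fh*fw*C).

    Stride is fixed at 1; pooling handles all downsampling in this
    architecture.
    """
    b, h, w, c = x.shape
    oh, ow = h - fh + 1, w - fw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, oh, ow, fh, fw, c),
        strides=(s0, s1, s2, s1, s2, s3),
        writeable=False,
    )
    return cols.reshape(b * oh * ow, fh * fw * c), oh, ow


def _col2im(dcols: np.ndarray, padded_shape: tuple, fh: int, fw: int, oh: int, ow: int) -> np.ndarray:
    b, h, w, c = padded_shape
    dx = np.zeros(padded_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(b, oh, ow, fh, fw, c)
    for i in range(fh):
        for j in range(fw):
            dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
    return dx


class Conv2D(Layer):
    """Stride-1 2-D convolution (cross-correlation), HWIO weight layout.

    ``padding="same"`` requires an odd kernel and pads (f-1)/2 per side so
    the output spatial size equals the input's; ``padding="valid"`` gives
    the n + 2p - f + 1 contract with p = 0.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        padding: str = "same",
        use_bias: bool = True,
        name: str = "conv",
        rng: np.random.Generator | None = None,
    ):
        if in_channels < 1 or out_channels < 1 or kernel_size < 1:
            raise ValueError("channel and kernel counts must be >= 1")
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.padding = padding
        self.pad = (kernel_size - 1) // 2 if padding == "same" else 0
        fan_in = kernel_size * kernel_size * in_channels
        self.weight = Parameter(
            he_uniform(rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in),
            f"{name}.weight",
        )
        self.use_bias = use_bias
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias") if use_bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.use_bias else [])

    def forward(self, x, training=False):
        if x.ndim != 4:
            raise ValueError(f"expected rank-4 input, got shape {x.shape}")
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"input has {x.shape[-1]} channels, layer expects {self.in_channels}"
            )
        f = self.kernel_size
        if self.pad:
            xp = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        else:
            xp = x
        cols, oh, ow = _im2col(xp, f, f)
        wmat = self.weight.value.reshape(f * f * self.in_channels, self.out_channels)
        y = cols @ wmat
        if self.use_bias:
            y += self.bias.value
        y = y.reshape(x.shape[0], oh, ow, self.out_channels)
        self._cache = (cols, xp.shape, oh, ow, x.shape[0])
        return y

    def backward(self, dy):
        cols, padded_shape, oh, ow, b = self._cache
        f = self.kernel_size
        dyf = dy.reshape(b * oh * ow, self.out_channels)
        wmat = self.weight.value.reshape(f * f * self.in_channels, self.out_channels)
        self.weight.grad += (cols.T @ dyf).reshape(self.weight.value.shape)
        if self.use_bias:
            self.bias.grad += dyf.sum(axis=0)
        dcols = dyf @ wmat.T
        dxp = _col2im(dcols, padded_shape, f, f, oh, ow)
        if self.pad:
            return dxp[:, self.pad : -self.pad, self.pad : -self.pad, :]
        return dxp


class ConvTranspose2x2(Layer):
    """2x2-kernel, stride-2 transpose convolution (exact 2x upsampling).

    With kernel = stride the output patches do not overlap, so the
    operation is a per-pixel linear map into disjoint 2x2 output tiles.
    """

    def __init__(self, in_channels: int, out_channels: int, use_bias: bool = True,
                 name: str = "upconv", rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(
            he_uniform(rng, (2, 2, in_channels, out_channels), in_channels),
            f"{name}.weight",
        )
        self.use_bias = use_bias
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias") if use_bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.use_bias else [])

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"input has {x.shape[-1]} channels, layer expects {self.in_channels}"
            )
        b, h, w, _ = x.shape
        y = np.einsum("bijc,uvco->biujvo", x, self.weight.value, optimize=True)
        y = y.reshape(b, 2 * h, 2 * w, self.out_channels)
        if self.use_bias:
            y += self.bias.value
        self._cache = (x, h, w, b)
        return y

    def backward(self, dy):
        x, h, w, b = self._cache
        dyr = dy.reshape(b, h, 2, w, 2, self.out_channels)
        self.weight.grad += np.einsum("bijc,biujvo->uvco", x, dyr, optimize=True)
        if self.use_bias:
            self.bias.grad += dy.sum(axis=(0, 1, 2))
        return np.einsum("biujvo,uvco->bijc", dyr, self.weight.value, optimize=True)


class BatchNorm(Layer):
    """Per-channel batch normalization with learnable scale/shift.

    Normalizes over (batch, height, width) with the batch statistics when
    training and with running statistics at inference. Running stats are
    exponential moving averages with the given momentum.
    """

    def __init__(self, channels: int, epsilon: float = 1e-3, momentum: float = 0.9,
                 name: str = "bn"):
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.channels = channels
        self.epsilon = epsilon
        self.momentum = momentum
        self.scale = Parameter(np.ones(channels), f"{name}.scale")
        self.shift = Parameter(np.zeros(channels), f"{name}.shift")
        self.running_mean = Parameter(np.zeros(channels), f"{name}.running_mean", trainable=False)
        self.running_var = Parameter(np.ones(channels), f"{name}.running_var", trainable=False)
        self._cache = None

    def parameters(self):
        return [self.scale, self.shift, self.running_mean, self.running_var]

    def forward(self, x, training=False):
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean.value = m * self.running_mean.value + (1 - m) * mean
            self.running_var.value = m * self.running_var.value + (1 - m) * var
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        inv_std = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape)
        return xhat * self.scale.value + self.shift.value

    def backward(self, dy):
        xhat, inv_std, shape = self._cache
        axes = (0, 1, 2)
        n = shape[0] * shape[1] * shape[2]
        self.scale.grad += (dy * xhat).sum(axis=axes)
        self.shift.grad += dy.sum(axis=axes)
        dxhat = dy * self.scale.value
        # standard batch-norm gradient; collapses to dxhat*inv_std at inference-like stats
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(b, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (b, h, w, c) = self._cache
        dxr = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(b, h, w, c)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Parameter` objects."""

    def __init__(self, params, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = learning_rate
        self.beta1, self.beta2, self.epsilon = beta1, beta2, epsilon
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.epsilon)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
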