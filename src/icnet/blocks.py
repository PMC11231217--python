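"""The three computational blocks of the segmentation network.

* :class:`MABlock` — conv(3x3) -> batch norm -> ReLU -> conv(3x3); the
  encoder/decoder workhorse.
* :class:`FCNBlock` — three chained convolution branches with ReLU, tanh
  and sigmoid activations, concatenated channel-wise (3x width) and
  merged by a final ReLU convolution; used at the bottleneck.
* :class:`AttentionBlock` — additive attention gate: 1x1 convolutions of
  the skip (theta) and gating (phi) features, ReLU, 1x1 mask convolution,
  sigmoid mask multiplied into the theta-transformed skip.

Everything is built on the stride-1 convolution primitive whose output
size obeys v = n + 2p - f + 1. Functional wrappers (:func:`conv2d`,
:func:`ma_block`, :func:`fcn_block`, :func:`attention_block`) mirror the
block classes for one-shot use and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    BatchNorm,
    Conv2D,
    Layer,
    Parameter,
    ReLU,
    Sigmoid,
    Tanh,
)

__all__ = [
    "ConvSpec",
    "as_feature_map",
    "conv2d",
    "MABlock",
    "FCNBlock",
    "AttentionBlock",
    "ma_block",
    "fcn_block",
    "attention_block",
]


@dataclass(frozen=True)
class ConvSpec:
    """Hyperparameters of one convolution.

    The spatial contract for stride 1 is ``v = n + 2p - f + 1`` where
    *n* is the input size, *p* the per-side padding and *f* the kernel
    size; :meth:`output_size` generalizes to stride s.
    """

    kernel_height: int
    kernel_width: int
    in_channels: int
    out_channels: int
    padding: int = 0
    stride: int = 1
    use_bias: bool = True

    def __post_init__(self):
        for field in ("kernel_height", "kernel_width", "in_channels", "out_channels", "stride"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1, got {getattr(self, field)}")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    def output_size(self, n: int) -> int:
        v = (n + 2 * self.padding - self.kernel_height) // self.stride + 1
        if v < 1:
            raise ValueError(f"kernel {self.kernel_height} too large for input size {n}")
        return v


def as_feature_map(x: np.ndarray) -> np.ndarray:
    """Validate a rank-4 (batch, height, width, channels) feature map."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"feature map must be rank 4 (B,H,W,C), got shape {x.shape}")
    if any(d < 1 for d in x.shape):
        raise ValueError(f"all feature-map dimensions must be >= 1, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def conv2d(x: np.ndarray, spec: ConvSpec, weights: np.ndarray,
           bias: np.ndarray | None = None) -> np.ndarray:
    """Direct 2-D convolution (cross-correlation) under a :class:`ConvSpec`.

    ``weights`` has HWIO layout ``(kernel_height, kernel_width,
    in_channels, out_channels)``. Output spatial size follows the
    v = n + 2p - f + 1 contract (generalized for stride); output is
    linear in ``x`` for fixed weights.
    """
    x = as_feature_map(x)
    weights = np.asarray(weights, dtype=np.float64)
    expected = (spec.kernel_height, spec.kernel_width, spec.in_channels, spec.out_channels)
    if weights.shape != expected:
        raise ValueError(f"weights shape {weights.shape} != spec shape {expected}")
    if x.shape[-1] != spec.in_channels:
        raise ValueError(f"input has {x.shape[-1]} channels, spec expects {spec.in_channels}")
    b, h, w, _ = x.shape
    p, s = spec.padding, spec.stride
    fh, fw = spec.kernel_height, spec.kernel_width
    oh = spec.output_size(h)
    ow = (w + 2 * p - fw) // s + 1
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
    s0, s1, s2, s3 = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, oh, ow, fh, fw, spec.in_channels),
        strides=(s0, s1 * s, s2 * s, s1, s2, s3),
        writeable=False,
    )
    y = np.tensordot(patches, weights, axes=([3, 4, 5], [0, 1, 2]))
    if spec.use_bias and bias is not None:
        y = y + np.asarray(bias, dtype=np.float64)
    return y


def same_spec(kernel: int, cin: int, cout: int) -> ConvSpec:
    """A stride-1 'same'-padding spec: p = (f-1)/2 keeps v = n."""
    if kernel % 2 == 0:
        raise ValueError("'same' padding requires an odd kernel size")
    return ConvSpec(kernel, kernel, cin, cout, padding=(kernel - 1) // 2, stride=1)


class MABlock(Layer):
    """conv(3x3, filters) -> batch norm -> ReLU -> conv(3x3, filters).

    Spatial size is preserved ('same' padding); output channel count
    equals ``filters``. Batch norm normalizes per channel and applies a
    learned scale/shift.
    """

    def __init__(self, in_channels: int, filters: int,
                 rng: np.random.Generator | None = None,
                 bn_epsilon: float = 1e-3, name: str = "ma"):
        if filters < 1:
            raise ValueError(f"filters must be >= 1, got {filters}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.filters = filters
        self.conv1 = Conv2D(in_channels, filters, 3, name=f"{name}.conv1", rng=rng)
        self.bn = BatchNorm(filters, epsilon=bn_epsilon, name=f"{name}.bn")
        self.relu = ReLU()
        self.conv2 = Conv2D(filters, filters, 3, name=f"{name}.conv2", rng=rng)

    def parameters(self):
        return self.conv1.parameters() + self.bn.parameters() + self.conv2.parameters()

    def forward(self, x, training=False):
        y = self.conv1(x, training)
        y = self.bn(y, training)
        y = self.relu(y, training)
        return self.conv2(y, training)

    def backward(self, dy):
        dy = self.conv2.backward(dy)
        dy = self.relu.backward(dy)
        dy = self.bn.backward(dy)
        return self.conv1.backward(dy)


class FCNBlock(Layer):
    """Multi-activation block: ReLU, tanh and sigmoid convolution branches.

    Sequential wiring (default): Y1 = ReLU(conv(x)), Y2 = tanh(conv(Y1)),
    Y3 = sigmoid(conv(Y2)). With ``parallel=True`` every branch reads the
    block input instead. The branches are concatenated channel-wise into
    a 3*filters-wide map and merged by a final ReLU convolution back to
    ``filters`` channels.
    """

    def __init__(self, in_channels: int, filters: int,
                 rng: np.random.Generator | None = None,
                 parallel: bool = False, name: str = "fcn"):
        if filters < 1:
            raise ValueError(f"filters must be >= 1, got {filters}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.filters = filters
        self.parallel = parallel
        branch_in = in_channels if parallel else filters
        self.conv_relu = Conv2D(in_channels, filters, 3, name=f"{name}.conv_relu", rng=rng)
        self.conv_tanh = Conv2D(branch_in, filters, 3, name=f"{name}.conv_tanh", rng=rng)
        self.conv_sigmoid = Conv2D(branch_in, filters, 3, name=f"{name}.conv_sigmoid", rng=rng)
        self.conv_merge = Conv2D(3 * filters, filters, 3, name=f"{name}.conv_merge", rng=rng)
        self.act1, self.act2, self.act3 = ReLU(), Tanh(), Sigmoid()
        self.act_out = ReLU()

    def parameters(self):
        return (self.conv_relu.parameters() + self.conv_tanh.parameters()
                + self.conv_sigmoid.parameters() + self.conv_merge.parameters())

    def forward(self, x, training=False):
        y1 = self.act1(self.conv_relu(x, training), training)
        src2 = x if self.parallel else y1
        y2 = self.act2(self.conv_tanh(src2, training), training)
        src3 = x if self.parallel else y2
        y3 = self.act3(self.conv_sigmoid(src3, training), training)
        y4 = np.concatenate([y1, y2, y3], axis=-1)
        self._shapes = (y1.shape[-1], y2.shape[-1], y3.shape[-1])
        return self.act_out(self.conv_merge(y4, training), training)

    def backward(self, dy):
        dy = self.conv_merge.backward(self.act_out.backward(dy))
        c1, c2, _ = self._shapes
        d1, d2, d3 = dy[..., :c1], dy[..., c1 : c1 + c2], dy[..., c1 + c2 :]
        d3 = self.conv_sigmoid.backward(self.act3.backward(d3))
        if self.parallel:
            dx3, dx2_extra = d3, 0.0
        else:
            dx3, dx2_extra = 0.0, d3
        d2 = self.conv_tanh.backward(self.act2.backward(d2 + dx2_extra))
        if self.parallel:
            dx2, d1_extra = d2, 0.0
        else:
            dx2, d1_extra = 0.0, d2
        dx1 = self.conv_relu.backward(self.act1.backward(d1 + d1_extra))
        return dx1 + dx2 + dx3

    def intermediate_width(self) -> int:
        """Channel count of the pre-merge concatenated map (3 * filters)."""
        return 3 * self.filters


class AttentionBlock(Layer):
    """Additive attention gate between a skip connection and a gating signal.

    T = 1x1 conv(skip, inter_channels); P = 1x1 conv(gating, inter_channels);
    A = ReLU(T + P); M = sigmoid(1x1 conv(A, 1)); output Y = M * T with the
    single-channel mask broadcast over channels. With
    ``gate_raw_skip=True`` the mask multiplies the untransformed skip
    instead. Mask values are strictly inside (0, 1).
    """

    def __init__(self, skip_channels: int, gating_channels: int, inter_channels: int,
                 rng: np.random.Generator | None = None,
                 gate_raw_skip: bool = False, name: str = "att"):
        if inter_channels < 1:
            raise ValueError(f"inter_channels must be >= 1, got {inter_channels}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.gate_raw_skip = gate_raw_skip
        self.theta = Conv2D(skip_channels, inter_channels, 1, name=f"{name}.theta", rng=rng)
        self.phi = Conv2D(gating_channels, inter_channels, 1, name=f"{name}.phi", rng=rng)
        self.psi = Conv2D(inter_channels, 1, 1, name=f"{name}.psi", rng=rng)
        self.relu = ReLU()
        self.sigmoid = Sigmoid()
        self.out_channels = skip_channels if gate_raw_skip else inter_channels

    def parameters(self):
        return self.theta.parameters() + self.phi.parameters() + self.psi.parameters()

    def forward(self, skip, gating, training=False):
        if skip.shape[1:3] != gating.shape[1:3]:
            raise ValueError(
                f"skip spatial size {skip.shape[1:3]} != gating {gating.shape[1:3]}"
            )
        t = self.theta(skip, training)
        p = self.phi(gating, training)
        a = self.relu(t + p, training)
        mask = self.sigmoid(self.psi(a, training), training)
        target = skip if self.gate_raw_skip else t
        self._cache = (t, mask, target, skip)
        return mask * target

    def __call__(self, skip, gating, training=False):
        return self.forward(skip, gating, training)

    def backward(self, dy):
        t, mask, target, skip = self._cache
        dtarget = dy * mask
        dmask = (dy * target).sum(axis=-1, keepdims=True)
        da = self.psi.backward(self.sigmoid.backward(dmask))
        da = self.relu.backward(da)
        dt = da + (0.0 if self.gate_raw_skip else dtarget)
        dskip = self.theta.backward(dt)
        if self.gate_raw_skip:
            dskip = dskip + dtarget
        dgating = self.phi.backward(da)
        return dskip, dgating

    def last_mask(self) -> np.ndarray:
        """Attention mask from the most recent forward pass, shape (B,H,W,1)."""
        return self._cache[1]


def _seeded(params):
    if isinstance(params, (int, np.integer)):
        return np.random.default_rng(int(params))
    if params is None:
        return np.random.default_rng(0)
    return params


def ma_block(x, filters, params=None):
    """One-shot MA block application; ``params`` is an MABlock, rng or seed."""
    x = as_feature_map(x)
    block = params if isinstance(params, MABlock) else MABlock(x.shape[-1], filters, rng=_seeded(params))
    return block(x)


def fcn_block(x, filters, params=None, parallel: bool = False):
    """One-shot FCN block application; ``params`` is an FCNBlock, rng or seed."""
    x = as_feature_map(x)
    block = params if isinstance(params, FCNBlock) else FCNBlock(
        x.shape[-1], filters, rng=_seeded(params), parallel=parallel)
    return block(x)


def attention_block(skip, gating, inter_channels, params=None):
    """One-shot attention gate; ``params`` is an AttentionBlock, rng or seed."""
    skip = as_feature_map(skip)
    gating = as_feature_map(gating)
    block = params if isinstance(params, AttentionBlock) else AttentionBlock(
        skip.shape[-1], gating.shape[-1], inter_channels, rng=_seeded(params))
    return block(skip, gating)
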