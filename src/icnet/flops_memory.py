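"""FLOP and parameter-memory accounting.

The canonical convolution cost is the block-level formula
``2 * K * Cin * Cout * Hout * Wout`` (K = kernel footprint, a
multiply-accumulate counted as two operations). A layer-level variant
that omits the input channels (``2 * Cout * K * Hout * Wout``) is
available behind ``per_kernel=True``.

Block totals count only the convolutions — MA: 2, attention: 3 (theta,
phi, mask), FCN: 4 (three branches plus merge); elementwise additions,
activations, multiplications and pooling are counted as zero. The
reference dimensions ``K=8, Cin=Cout=64, Hout=Wout=128`` make one
convolution cost exactly 2^30 FLOPs and are a reconstruction chosen so
the three block totals (2, 3 and 4 convolutions) come out at
2,147,483,648 / 3,221,225,472 / 4,294,967,296 FLOPs, summing to
9,663,676,416.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ModelConfig

__all__ = ["LayerCost", "conv_flops", "dense_flops", "block_flops",
           "memory_estimate", "model_flop_table", "REFERENCE_DIMS",
           "BLOCK_CONV_COUNTS"]

REFERENCE_DIMS = {"K": 8, "Cin": 64, "Cout": 64, "Hout": 128, "Wout": 128}
BLOCK_CONV_COUNTS = {"MA": 2, "Attention": 3, "FCN": 4}


@dataclass(frozen=True)
class LayerCost:
    """FLOPs and parameter count of one named layer."""

    name: str
    flops: int
    params: int

    def __post_init__(self):
        if self.flops < 0 or self.params < 0:
            raise ValueError("costs must be non-negative")


def conv_flops(K: int, Cin: int, Cout: int, Hout: int, Wout: int,
               per_kernel: bool = False) -> int:
    """FLOPs of one convolution: 2*K*Cin*Cout*Hout*Wout.

    ``per_kernel=True`` switches to the layer-level variant
    2*Cout*K*Hout*Wout that counts kernels rather than
    kernel-times-input-channel products.
    """
    for name, v in (("K", K), ("Cin", Cin), ("Cout", Cout), ("Hout", Hout), ("Wout", Wout)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if per_kernel:
        return 2 * Cout * K * Hout * Wout
    return 2 * K * Cin * Cout * Hout * Wout


def dense_flops(n_in: int, n_out: int) -> int:
    """FLOPs of one fully connected layer: 2 * n_in * n_out."""
    return 2 * n_in * n_out


def block_flops(kind: str, dims: dict | None = None) -> int:
    """Total FLOPs of one block at the given (default: reference) dimensions.

    Sums ``conv_flops`` over the block's convolutions: 2 for MA, 3 for
    attention, 4 for FCN. Elementwise operations are excluded.
    """
    if kind not in BLOCK_CONV_COUNTS:
        raise ValueError(f"unknown block kind {kind!r}; expected one of {sorted(BLOCK_CONV_COUNTS)}")
    d = dict(REFERENCE_DIMS)
    if dims:
        d.update(dims)
    one = conv_flops(d["K"], d["Cin"], d["Cout"], d["Hout"], d["Wout"])
    return BLOCK_CONV_COUNTS[kind] * one


def memory_estimate(trainable: int, non_trainable: int, bytes_per_param: int = 4) -> float:
    """Parameter memory in MB: (trainable + non_trainable) * bytes / 2^20."""
    if trainable < 0 or non_trainable < 0:
        raise ValueError("parameter counts must be >= 0")
    if bytes_per_param not in (2, 4, 8):
        raise ValueError("bytes_per_param must be one of {2, 4, 8}")
    return (trainable + non_trainable) * bytes_per_param / 2**20


def _conv_entry(name, k, cin, cout, h, w, bias=True):
    return LayerCost(name, conv_flops(k * k, cin, cout, h, w),
                     k * k * cin * cout + (cout if bias else 0))


def model_flop_table(config: ModelConfig) -> list:
    """Per-convolution FLOP/parameter inventory of the assembled network.

    Walks the same graph ``build_model`` constructs (encoder MA blocks,
    FCN bottleneck, transpose-conv + attention + MA decoder, 1x1 head)
    and prices every convolution at its actual output size.
    """
    f = config.filters
    h, w = config.input_height, config.input_width
    rows = []
    cin = config.in_channels
    for level, nf in enumerate(f, start=1):
        rows.append(_conv_entry(f"enc{level}.conv1", 3, cin, nf, h, w))
        rows.append(_conv_entry(f"enc{level}.conv2", 3, nf, nf, h, w))
        cin = nf
        if level < 5:
            h, w = h // 2, w // 2
    nf = f[4]
    rows.append(_conv_entry("fcn.conv_relu", 3, nf, nf, h, w))
    rows.append(_conv_entry("fcn.conv_tanh", 3, nf, nf, h, w))
    rows.append(_conv_entry("fcn.conv_sigmoid", 3, nf, nf, h, w))
    rows.append(_conv_entry("fcn.conv_merge", 3, 3 * nf, nf, h, w))
    gating = nf
    for level in (4, 3, 2, 1):
        nf = f[level - 1]
        h, w = h * 2, w * 2
        # 2x2 stride-2 transpose conv: output tiles are disjoint, so each
        # output pixel sees a single kernel tap (footprint 1), but the layer
        # still stores a 2x2 kernel.
        rows.append(LayerCost(f"up{level}", conv_flops(1, gating, nf, h, w),
                              2 * 2 * gating * nf + nf))
        rows.append(_conv_entry(f"att{level}.theta", 1, nf, nf, h, w))
        rows.append(_conv_entry(f"att{level}.phi", 1, nf, nf, h, w))
        rows.append(_conv_entry(f"att{level}.psi", 1, nf, 1, h, w))
        rows.append(_conv_entry(f"dec{level}.conv1", 3, 2 * nf, nf, h, w))
        rows.append(_conv_entry(f"dec{level}.conv2", 3, nf, nf, h, w))
        gating = nf
    rows.append(_conv_entry("head", 1, f[0], config.num_classes, h, w))
    return rows
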