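"""Structural analyses: receptive-field arithmetic, valid-convolution size
arithmetic, encoder activation heat-maps, and connected-component
post-filtering of predicted masks.

The receptive-field recurrence walks a layer trace (kernel k, stride s,
dilation d) accumulating

    rf   <- rf + (k - 1) * d * jump
    jump <- jump * s

from rf = jump = 1.  On the classical U-Net contracting path (two 3x3
stride-1 convolutions per level, 2x2 stride-2 max pooling between the
five levels, plus the two bottleneck convolutions) this yields a 140-pixel
side: each element of the deepest encoder feature can see at most a
140 x 140 input region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InputError
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class Layer:
    kernel: int
    stride: int = 1
    dilation: int = 1

    def __post_init__(self):
        if self.kernel < 1 or self.stride < 1 or self.dilation < 1:
            raise InputError("kernel/stride/dilation must be >= 1")


LayerTrace = list[Layer]


def unet_encoder_trace(levels: int = 5, convs_per_level: int = 2) -> LayerTrace:
    """Contracting path of the classical U-Net: per level ``convs_per_level``
    3x3 stride-1 convolutions, with a 2x2 stride-2 pooling between levels."""
    trace: LayerTrace = []
    for lvl in range(levels):
        if lvl > 0:
            trace.append(Layer(kernel=2, stride=2))
        trace.extend(Layer(kernel=3) for _ in range(convs_per_level))
    return trace


def sru_encoder_trace(levels: int = 6) -> LayerTrace:
    """Spatial trace of the split-attention encoder: per level one 3x3
    convolution widens the receptive field (the 1x1 convolutions do not),
    with 2x2 stride-2 pooling between levels."""
    trace: LayerTrace = []
    for lvl in range(levels):
        if lvl > 0:
            trace.append(Layer(kernel=2, stride=2))
        trace.extend([Layer(kernel=1), Layer(kernel=3), Layer(kernel=1)])
    return trace


@dataclass
class RFReport:
    receptive_field: int
    jump: int
    table: list[dict]  # per-layer: kernel, stride, dilation, rf, jump


def receptive_field(trace: LayerTrace) -> RFReport:
    """Theoretical receptive-field side of one deepest-layer element."""
    if not trace:
        raise InputError("empty layer trace")
    rf, jump = 1, 1
    table = []
    for layer in trace:
        rf = rf + (layer.kernel - 1) * layer.dilation * jump
        jump = jump * layer.stride
        table.append(
            {
                "kernel": layer.kernel,
                "stride": layer.stride,
                "dilation": layer.dilation,
                "rf": rf,
                "jump": jump,
            }
        )
    return RFReport(receptive_field=rf, jump=jump, table=table)


def valid_conv_size(input_side: int, trace: LayerTrace) -> int:
    """Spatial side after unpadded ('valid') application of the trace."""
    side = input_side
    for i, layer in enumerate(trace):
        extent = (layer.kernel - 1) * layer.dilation + 1
        rem = side - extent
        if rem < 0:
            raise InputError(f"layer {i} ({layer}) consumes the whole input (side {side})")
        if rem % layer.stride:
            raise InputError(f"layer {i} ({layer}): ({side} - {extent}) not divisible by stride")
        side = rem // layer.stride + 1
    return side


def gradient_extent_oracle(trace: LayerTrace, input_side: int) -> int:
    """Empirical receptive-field side: build the trace as actual average-pool
    convolutions, backprop from the centre of the deepest map, and measure
    the nonzero-gradient extent on the input.  Independent of the
    recurrence: uses only the autodiff engine's primitives."""
    x = Tensor(np.zeros((1, 1, input_side, input_side), dtype=np.float32), requires_grad=True)
    h = x
    for layer in trace:
        if layer.stride == 1:
            w = Tensor(np.ones((1, 1, layer.kernel, layer.kernel), dtype=np.float32))
            h = F.conv2d(h, w, padding=(layer.kernel - 1) * layer.dilation // 2,
                         dilation=layer.dilation)
        elif layer.kernel == layer.stride == 2:
            h = F.avg_pool2d(h)
        else:
            raise InputError(f"oracle supports stride-1 layers and 2x2/s2 pooling, got {layer}")
    ci, cj = h.shape[2] // 2, h.shape[3] // 2
    g = np.zeros(h.shape, dtype=np.float32)
    g[0, 0, ci, cj] = 1.0
    h.backward(g)
    rows = np.nonzero(np.abs(x.grad[0, 0]).sum(axis=1))[0]
    cols = np.nonzero(np.abs(x.grad[0, 0]).sum(axis=0))[0]
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))


# ---------------------------------------------------------------- activation map
def activation_heatmap(model, image: np.ndarray) -> np.ndarray:
    """Channel-mean of the deepest encoder feature, min-max normalized to
    [0,1] and bilinearly enlarged to the input resolution."""
    from . import nn  # local import to avoid cycle at module load

    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            feats = model.encode(Tensor(x))
            deep = feats[-1].data.mean(axis=1, keepdims=True)  # (B,1,h,w)
            up = F.bilinear_resize(Tensor(deep), (x.shape[2], x.shape[3])).data
    finally:
        model.train(was_training)
    out = up[0, 0]
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


# ------------------------------------------------------------- component filter
def keep_largest_component(
    mask: np.ndarray, cls: int, min_area: int | None = None, largest_only: bool = False
) -> np.ndarray:
    """Relabel small (or all but the largest) 8-connected components of
    class ``cls`` to background; other classes untouched.

    ``min_area`` defaults to 0.1% of the image pixels.
    """
    mask = np.asarray(mask)
    if min_area is None:
        min_area = max(int(0.001 * mask.size), 1)
    out = mask.copy()
    region = mask == cls
    lab, nlab = ndimage.label(region, structure=np.ones((3, 3)))
    if nlab == 0:
        return out
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    drop = sizes < min_area
    if largest_only:
        keep_idx = int(np.argmax(sizes))
        drop = np.ones(nlab, dtype=bool)
        drop[keep_idx] = sizes[keep_idx] < min_area
    kill = np.zeros(nlab + 1, dtype=bool)
    kill[1:] = drop
    out[kill[lab]] = 0
    return out
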