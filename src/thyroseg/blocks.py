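"""The network building blocks: split-attention residual block, atrous
spatial pyramid pooling (ASPP), deformable convolution, and the DASPP
composition that replaces ASPP's dilation-1 branch with a deformable conv
and adds a parallel wide deformable branch.

Design notes
------------
* Cardinality is fixed at 1 (no cardinal groups); only the radix split is
  used.
* Downsampling inside the split-attention block is done by average pooling
  placed after the first 1x1 convolution and at the start of the shortcut,
  so every convolution stays stride-1.
* The deformable convolution is DCNv3-flavoured: a shared 3x3 weight,
  per-location learned fractional offsets (one set of K = 9 points shared
  across channel groups) and per-point modulation scalars normalized as
  K * softmax over the K points, so that zero offset/modulation logits
  reproduce a standard convolution exactly.  Offset and modulation
  predictors are zero-initialized for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import functional as F
from .nn.tensor import Tensor


# --------------------------------------------------------------------- configs
@dataclass
class BlockConfig:
    """Split-attention residual block configuration (cardinality fixed at 1)."""

    in_channels: int
    out_channels: int
    radix: int = 2
    stride: int = 1
    reduction_factor: int = 4

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.radix < 1:
            raise ConfigurationError(f"radix must be >= 1, got {self.radix}")
        if self.stride not in (1, 2):
            raise ConfigurationError(f"stride must be 1 or 2, got {self.stride}")
        if self.reduction_factor < 1:
            raise ConfigurationError("reduction_factor must be positive")


@dataclass
class DilationSet:
    """Dilation rates for the pyramid branches; the first rate must be 1."""

    rates: tuple[int, ...] = (1, 6, 12, 18)
    include_global_pool: bool = True

    def __post_init__(self):
        rates = tuple(int(r) for r in self.rates)
        if len(rates) == 0 or any(r < 1 for r in rates):
            raise ConfigurationError("rates must be positive ints")
        if sorted(set(rates)) != list(rates):
            raise ConfigurationError("rates must be distinct and ascending")
        if rates[0] != 1:
            raise ConfigurationError("first dilation rate must be 1")
        self.rates = rates


@dataclass
class DeformableConvSpec:
    in_channels: int
    out_channels: int
    kernel: int = 3
    groups: int = 4

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ConfigurationError(f"kernel must be odd positive, got {self.kernel}")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ConfigurationError(
                f"groups={self.groups} must divide channels "
                f"({self.in_channels}->{self.out_channels})"
            )


def _conv_bn_relu(cin, cout, k, rng, dilation=1, groups=1):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, dilation=dilation, groups=groups, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


# ---------------------------------------------------------------- split-attention
class SplitAttentionBlock(nn.Module):
    """Residual block with a radix channel split and softmax attention.

    Main path: 1x1 conv -> (pool if stride 2) -> radix-split grouped 3x3
    conv -> split-attention recombination -> 1x1 conv; the shortcut is the
    identity or, when channels or resolution change, (pool) + 1x1 conv + BN.
    Attention weights come from the globally pooled split-sum through two
    1x1 transforms and a softmax across the radix axis, so they sum to 1
    per (location-free) channel; with radix = 1 the softmax of a singleton
    is exactly 1 and the block degenerates to a plain bottleneck residual.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        cin, cout, radix = cfg.in_channels, cfg.out_channels, cfg.radix
        mid = cout
        if mid % radix:
            raise ConfigurationError(
                f"radix {radix} must divide the split width {mid}"
            )
        inner = max(mid * radix // cfg.reduction_factor, 32)
        self.conv1 = _conv_bn_relu(cin, mid, 1, rng)
        self.conv3 = nn.Conv2d(mid, mid * radix, 3, groups=radix, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(mid * radix)
        self.relu = nn.ReLU()
        self.fc1 = _conv_bn_relu(mid, inner, 1, rng)
        self.fc2 = nn.Conv2d(inner, mid * radix, 1, rng=rng)
        self.conv2 = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if cin != cout or cfg.stride == 2:
            self.short_conv = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
            self.short_bn = nn.BatchNorm2d(cout)
        else:
            self.short_conv = None

    def attention_weights(self, x: Tensor) -> Tensor:
        """Radix attention weights (B, radix, mid, 1, 1); sum to 1 over radix."""
        _, w = self._main(x, want_attention=True)
        return w

    def _main(self, x: Tensor, want_attention: bool = False):
        cfg = self.cfg
        mid, radix = cfg.out_channels, cfg.radix
        h = self.conv1(x)
        if cfg.stride == 2:
            h = F.avg_pool2d(h)
        h = self.relu(self.bn3(self.conv3(h)))
        B, _, H, W = h.shape
        splits = h.reshape(B, radix, mid, H, W)
        gap = F.global_avg_pool(splits.sum(axis=1))  # (B, mid, 1, 1)
        a = self.fc2(self.fc1(gap))  # (B, mid*radix, 1, 1)
        a = F.softmax(a.reshape(B, radix, mid, 1, 1), axis=1)
        out = (splits * a).sum(axis=1)
        out = self.bn2(self.conv2(out))
        return out, (a if want_attention else None)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"block expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        main, _ = self._main(x)
        if self.short_conv is not None:
            s = x
            if self.cfg.stride == 2:
                s = F.avg_pool2d(s)
            s = self.short_bn(self.short_conv(s))
        else:
            s = x
        return (main + s).relu()


# ------------------------------------------------------------------- deformable
class DeformableConv2d(nn.Module):
    """3x3 deformable convolution with learned offsets and modulation.

    A zero-initialized 3x3 predictor yields per-location offsets
    (B, 2K, H, W) and modulation logits (B, K, H, W); modulation is
    K * softmax(logits) over the K points (sums to the constant K), so the
    freshly initialized layer computes exactly a standard 3x3 convolution.
    Samples outside the image read 0.
    """

    def __init__(self, spec: DeformableConvSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        k = spec.kernel
        self.K = k * k
        self.weight = Tensor(
            nn.kaiming_normal(rng, (spec.out_channels, spec.in_channels // spec.groups, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(spec.out_channels), requires_grad=True)
        self.offset_conv = nn.Conv2d(spec.in_channels, 2 * self.K, 3, rng=rng)
        self.mod_conv = nn.Conv2d(spec.in_channels, self.K, 3, rng=rng)
        for conv in (self.offset_conv, self.mod_conv):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return self._apply(x, deformable=True)

    def as_standard_conv(self, x: Tensor) -> Tensor:
        """The same weights applied as a plain 3x3 convolution (oracle path)."""
        return self._apply(x, deformable=False)

    def _apply(self, x: Tensor, deformable: bool) -> Tensor:
        spec = self.spec
        if x.shape[1] != spec.in_channels:
            raise ConfigurationError(
                f"deformable conv expects {spec.in_channels} channels, got {x.shape[1]}"
            )
        if not deformable:
            return F.conv2d(x, self.weight, self.bias, padding="same", groups=spec.groups)
        B, C, H, W = x.shape
        # offsets stored interleaved (dy_0, dx_0, dy_1, dx_1, ...)
        off = self.offset_conv(x)
        mod = F.softmax(self.mod_conv(x), axis=1) * float(self.K)  # (B,K,H,W)
        samp = F.deform_sample(x, off, kernel=spec.kernel)  # (B,K,C,H,W)
        samp = samp * mod.reshape(B, self.K, 1, H, W)
        # regroup channel-major so channel groups stay contiguous: (B, C*K, H, W)
        samp = samp.transpose(0, 2, 1, 3, 4).reshape(B, C * self.K, H, W)
        w11 = self.weight.reshape(
            spec.out_channels, (spec.in_channels // spec.groups) * self.K, 1, 1
        )
        return F.conv2d(samp, w11, self.bias, padding=0, groups=spec.groups)


# ------------------------------------------------------------------------- ASPP
def _auto_groups(cin: int, cout: int, preferred: int = 4) -> int:
    g = preferred
    while cin % g or cout % g:
        g -= 1
    return max(g, 1)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel 1x1 conv, 3x3 dilated convs
    at the configured rates, and an optional global-average-pool branch
    broadcast back to full resolution; fused by a 1x1 convolution.

    Default widths follow the bottleneck-halving convention: each branch is
    ``in_channels // 4`` wide and the fused output ``in_channels // 2``.
    """

    def __init__(
        self,
        in_channels: int,
        rates: DilationSet | None = None,
        branch_channels: int | None = None,
        out_channels: int | None = None,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        rates = rates or DilationSet()
        self.rates = rates
        bc = branch_channels or max(in_channels // 4, 1)
        self.out_channels = out_channels or max(in_channels // 2, 1)
        self.conv1 = _conv_bn_relu(in_channels, bc, 1, rng)
        self.dilated = [
            _conv_bn_relu(in_channels, bc, 3, rng, dilation=r) for r in rates.rates
        ]
        for i, m in enumerate(self.dilated):
            setattr(self, f"dil{i}", m)
        self.pool_proj = _conv_bn_relu(in_channels, bc, 1, rng) if rates.include_global_pool else None
        total = bc * (1 + len(rates.rates)) + (bc if self.pool_proj else 0)
        self.fuse = _conv_bn_relu(total, self.out_channels, 1, rng)
        self.drop = nn.Dropout(dropout, seed=int(rng.integers(2**31)))

    def _branches(self, x: Tensor) -> list[Tensor]:
        outs = [self.conv1(x)]
        outs += [m(x) for m in self.dilated]
        if self.pool_proj is not None:
            p = self.pool_proj(F.global_avg_pool(x))
            outs.append(F.bilinear_resize(p, (x.shape[2], x.shape[3])))
        return outs

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fuse(F.concat(self._branches(x), axis=1)))


class DASPP(nn.Module):
    """ASPP with the dilation-1 branch replaced by a deformable convolution
    and an extra wide parallel deformable branch (in -> in/2); all branch
    outputs are concatenated and fused by a 1x1 convolution."""

    def __init__(
        self,
        in_channels: int,
        rates: DilationSet | None = None,
        branch_channels: int | None = None,
        out_channels: int | None = None,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        rates = rates or DilationSet()
        self.rates = rates
        bc = branch_channels or max(in_channels // 4, 1)
        wide = max(in_channels // 2, 1)
        self.out_channels = out_channels or wide
        self.conv1 = _conv_bn_relu(in_channels, bc, 1, rng)
        self.deform1 = DeformableConv2d(
            DeformableConvSpec(in_channels, bc, groups=_auto_groups(in_channels, bc)), rng=rng
        )
        self.deform1_bn = nn.BatchNorm2d(bc)
        self.dilated = [
            _conv_bn_relu(in_channels, bc, 3, rng, dilation=r) for r in rates.rates[1:]
        ]
        for i, m in enumerate(self.dilated):
            setattr(self, f"dil{i}", m)
        self.pool_proj = _conv_bn_relu(in_channels, bc, 1, rng) if rates.include_global_pool else None
        self.parallel = DeformableConv2d(
            DeformableConvSpec(in_channels, wide, groups=_auto_groups(in_channels, wide)), rng=rng
        )
        self.parallel_bn = nn.BatchNorm2d(wide)
        total = bc * (1 + len(rates.rates)) + (bc if self.pool_proj else 0) + wide
        self.fuse = _conv_bn_relu(total, self.out_channels, 1, rng)
        self.drop = nn.Dropout(dropout, seed=int(rng.integers(2**31)))
        self.relu = nn.ReLU()

    def _branches(self, x: Tensor, deformable: bool = True) -> list[Tensor]:
        def dc(layer, bn, v):
            y = layer(v) if deformable else layer.as_standard_conv(v)
            return self.relu(bn(y))

        outs = [self.conv1(x), dc(self.deform1, self.deform1_bn, x)]
        outs += [m(x) for m in self.dilated]
        if self.pool_proj is not None:
            p = self.pool_proj(F.global_avg_pool(x))
            outs.append(F.bilinear_resize(p, (x.shape[2], x.shape[3])))
        outs.append(dc(self.parallel, self.parallel_bn, x))
        return outs

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fuse(F.concat(self._branches(x), axis=1)))

    def forward_with_standard_convs(self, x: Tensor) -> Tensor:
        """Oracle path: every deformable branch applied as a plain 3x3 conv."""
        return self.drop(self.fuse(F.concat(self._branches(x, deformable=False), axis=1)))
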