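"""Encoder–decoder segmentation architectures.

Four variants share one U-shaped skeleton:

* ``unet`` — the classical baseline: double 3x3 conv blocks, 2x2 max
  pooling, bilinear upsampling, depth 5 (widths 64…1024 by default).
* ``sru``  — every conv block replaced by a split-attention residual
  block, plus one extra top level (depth 6, widths 32…1024) to sharpen
  extraction of edges and small nodules.
* ``asru`` — ``sru`` with an ASPP module between encoder and decoder.
* ``dsru`` — ``sru`` with DASPP (deformable pyramid) between encoder and
  decoder: ŷ = Decoder(f₁…f₋₁, DASPP(f_deepest)).

The decoder mirrors the encoder level-for-level: bilinear (or nearest)
x2 upsampling, concatenation with the skip feature, then the level's
block; a final 1x1 convolution produces per-class logits at the input
resolution.  Convolutions are padded ('same') throughout, so input height
and width only need to be divisible by 2**(depth-1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .blocks import ASPP, DASPP, BlockConfig, DilationSet, SplitAttentionBlock
from .exceptions import ConfigurationError, InputError
from .nn import functional as F
from .nn.tensor import Tensor

logger = logging.getLogger(__name__)

VARIANTS = ("unet", "sru", "asru", "dsru")


@dataclass
class ModelConfig:
    variant: str = "dsru"
    in_channels: int = 1
    num_classes: int = 3
    base_width: int | None = None  # default: 64 for unet, 32 for the depth-6 variants
    depth: int | None = None  # default: 5 for unet, 6 otherwise
    radix: int = 2
    dilation_rates: tuple[int, ...] = (1, 6, 12, 18)
    include_global_pool: bool = True
    dropout: float = 0.5
    upsample: str = "bilinear"  # or "nearest"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if self.base_width is None:
            self.base_width = 64 if self.variant == "unet" else 32
        if self.depth is None:
            self.depth = 5 if self.variant == "unet" else 6
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.upsample not in ("bilinear", "nearest"):
            raise ConfigurationError(f"unknown upsample mode {self.upsample!r}")
        self.dilation_rates = tuple(self.dilation_rates)

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.depth)]


class _DoubleConv(nn.Module):
    """Two padded 3x3 conv + BN + ReLU stages (the original U-Net block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
            nn.Conv2d(cout, cout, 3, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        )

    def forward(self, x):
        return self.block(x)


class SegmentationModel(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        widths = cfg.widths
        d = cfg.depth

        def make_block(cin, cout):
            if cfg.variant == "unet":
                return _DoubleConv(cin, cout, rng)
            return SplitAttentionBlock(BlockConfig(cin, cout, radix=cfg.radix), rng=rng)

        self.enc = [make_block(cfg.in_channels if i == 0 else widths[i - 1], widths[i]) for i in range(d)]
        for i, m in enumerate(self.enc):
            setattr(self, f"enc{i}", m)

        rates = DilationSet(cfg.dilation_rates, cfg.include_global_pool)
        if cfg.variant == "asru":
            self.pyramid = ASPP(widths[-1], rates, dropout=cfg.dropout, rng=rng)
        elif cfg.variant == "dsru":
            self.pyramid = DASPP(widths[-1], rates, dropout=cfg.dropout, rng=rng)
        else:
            self.pyramid = None
        deep = self.pyramid.out_channels if self.pyramid else widths[-1]

        self.dec = []
        prev = deep
        for i in range(d - 2, -1, -1):  # deepest decoder level first
            self.dec.append(make_block(prev + widths[i], widths[i]))
            prev = widths[i]
        for i, m in enumerate(self.dec):
            setattr(self, f"dec{i}", m)
        self.head = nn.Conv2d(widths[0], cfg.num_classes, 1, rng=rng)

    # ------------------------------------------------------------------ passes
    def _check_input(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise InputError(f"expected (B,C,H,W) input, got shape {x.shape}")
        if x.shape[1] == 3 and self.cfg.in_channels == 1:
            logger.info("averaging 3-channel input down to 1 channel")
            x = x.mean(axis=1, keepdims=True)
        if x.shape[1] != self.cfg.in_channels:
            raise InputError(f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        m = 2 ** (self.cfg.depth - 1)
        if x.shape[2] % m or x.shape[3] % m:
            raise InputError(
                f"spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {m} "
                f"(depth {self.cfg.depth})"
            )
        return x

    def encode(self, x: Tensor) -> list[Tensor]:
        """Encoder features shallow -> deep (spatial halves, width doubles)."""
        x = self._check_input(x)
        feats = []
        for i, block in enumerate(self.enc):
            if i > 0:
                x = F.max_pool2d(x)
            x = block(x)
            feats.append(x)
        return feats

    def _upsample(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        if self.cfg.upsample == "bilinear":
            return F.bilinear_resize(x, hw)
        B, C, H, W = x.shape
        reps = x.reshape(B, C, H, 1, W, 1)
        ones = Tensor(np.ones((1, 1, 1, hw[0] // H, 1, hw[1] // W), dtype=np.float32))
        return (reps * ones).reshape(B, C, hw[0], hw[1])

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encode(x)
        h = self.pyramid(feats[-1]) if self.pyramid else feats[-1]
        for block, skip in zip(self.dec, feats[-2::-1]):
            h = self._upsample(h, (skip.shape[2], skip.shape[3]))
            h = block(F.concat([skip, h], axis=1))
        return self.head(h)

    def predict_classes(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward + per-pixel argmax -> label mask(s)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(Tensor(x))
        finally:
            self.train(was_training)
        return np.argmax(logits.data, axis=1).astype(np.uint8)

    # -------------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **state)


def build_model(cfg: ModelConfig) -> SegmentationModel:
    return SegmentationModel(cfg)


def load_model(path) -> SegmentationModel:
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    raw = state.pop("__config__", None)
    if raw is None:
        raise InputError(f"{path} is not a model checkpoint (missing embedded config)")
    cfg_dict = json.loads(bytes(raw.tobytes()).decode())
    cfg_dict["dilation_rates"] = tuple(cfg_dict["dilation_rates"])
    model = SegmentationModel(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    return model.eval()  # checkpoints load inference-ready
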