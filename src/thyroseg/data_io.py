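"""Image/mask I/O, letterbox preprocessing and training-time augmentation.

Dataset layout: ``images/*.png`` and ``masks/*.png`` paired by stem plus a
``manifest.csv`` with columns ``id,split``.  Masks are single-channel PNGs
with literal values 0 (background), 1 (gland), 2 (nodule).

The letterbox op resizes an image so the longer side equals the target
side (aspect ratio preserved; the short side rounds half-up), then pads
with zeros, split symmetrically with the odd pixel on the bottom/right.
The stored :class:`ResizeRecord` makes the inverse mapping exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import InputError

VALID_LABELS = frozenset({0, 1, 2})


@dataclass
class Sample:
    image: np.ndarray  # float32 in [0,1], (H,W)
    mask: np.ndarray  # uint8 in {0,1,2}, (H,W)
    id: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise InputError(
                f"image {self.image.shape} and mask {self.mask.shape} dims differ"
            )


@dataclass
class ResizeRecord:
    original_size: tuple[int, int]  # (h, w)
    scale: float
    pad: tuple[int, int, int, int]  # top, bottom, left, right
    side: int


@dataclass
class AugmentationConfig:
    """Per-transform apply probabilities and ranges (ultrasound-plausible defaults)."""

    p_brightness: float = 0.5
    p_contrast: float = 0.5
    p_mirror: float = 0.5
    p_rotation: float = 0.5
    p_crop: float = 0.5
    p_stretch: float = 0.5
    brightness_delta: float = 0.2
    contrast_range: tuple[float, float] = (0.8, 1.25)
    rotation_deg: float = 15.0
    crop_keep: float = 0.8  # minimum kept fraction per axis
    stretch_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        for name in ("p_brightness", "p_contrast", "p_mirror", "p_rotation", "p_crop", "p_stretch"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be in [0,1], got {p}")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(p_brightness=0, p_contrast=0, p_mirror=0, p_rotation=0, p_crop=0, p_stretch=0)


# ----------------------------------------------------------------------- resize
def _resize_bilinear(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    H, W = arr.shape
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return arr.astype(np.float32, copy=True)

    def axis_idx(n_in, n_out):
        src = np.clip((np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        return i0, np.minimum(i0 + 1, n_in - 1), (src - i0).astype(np.float32)

    y0, y1, ty = axis_idx(H, Ho)
    x0, x1, tx = axis_idx(W, Wo)
    rows = arr[y0, :] * (1 - ty)[:, None] + arr[y1, :] * ty[:, None]
    return (rows[:, x0] * (1 - tx)[None, :] + rows[:, x1] * tx[None, :]).astype(np.float32)


def _resize_nearest(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    H, W = arr.shape
    Ho, Wo = out_hw
    yi = np.clip(np.floor((np.arange(Ho) + 0.5) * (H / Ho)).astype(int), 0, H - 1)
    xi = np.clip(np.floor((np.arange(Wo) + 0.5) * (W / Wo)).astype(int), 0, W - 1)
    return arr[np.ix_(yi, xi)]


# --------------------------------------------------------------------------- IO
def load_sample(image_path, mask_path) -> Sample:
    """Read a grayscale image (multi-channel collapsed by mean) and its mask."""
    img = np.asarray(Image.open(image_path))
    scale = 255.0 if img.dtype == np.uint8 else 1.0
    if img.ndim == 3:
        img = img.mean(axis=2)
    image = img.astype(np.float32) / scale
    mask = np.asarray(Image.open(mask_path))
    if mask.ndim == 3:
        mask = mask[..., 0]
    bad = sorted(set(np.unique(mask).tolist()) - VALID_LABELS)
    if bad:
        raise InputError(f"mask {mask_path} contains labels outside {{0,1,2}}: {bad}")
    if image.shape != mask.shape:
        raise InputError(
            f"image {image.shape} and mask {mask.shape} dims differ for {image_path}"
        )
    return Sample(image=image, mask=mask.astype(np.uint8), id=Path(image_path).stem)


def save_sample(sample: Sample, images_dir, masks_dir) -> None:
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(images_dir / f"{sample.id}.png")
    Image.fromarray(sample.mask, mode="L").save(masks_dir / f"{sample.id}.png")


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as f:
        return list(csv.DictReader(f))


def write_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as f:
        wr = csv.DictWriter(f, fieldnames=list(rows[0].keys()))
        wr.writeheader()
        wr.writerows(rows)


def load_dataset(root, split: str | None = None) -> list[Sample]:
    root = Path(root)
    rows = read_manifest(root / "manifest.csv")
    if split is not None:
        rows = [r for r in rows if r["split"] == split]
    return [
        load_sample(root / "images" / f"{r['id']}.png", root / "masks" / f"{r['id']}.png")
        for r in rows
    ]


# ---------------------------------------------------------------------- letterbox
def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def letterbox(sample: Sample, side: int = 512) -> tuple[Sample, ResizeRecord]:
    """Aspect-preserving resize to ``side`` on the long side + symmetric zero fill."""
    h, w = sample.image.shape
    if h == 0 or w == 0:
        raise InputError("degenerate zero-pixel input")
    scale = side / max(h, w)
    if h >= w:
        nh, nw = side, max(_round_half_up(w * scale), 1)
    else:
        nh, nw = max(_round_half_up(h * scale), 1), side
    image = _resize_bilinear(sample.image, (nh, nw))
    mask = _resize_nearest(sample.mask, (nh, nw))
    pt = (side - nh) // 2
    pb = side - nh - pt
    pl = (side - nw) // 2
    pr = side - nw - pl
    image = np.pad(image, ((pt, pb), (pl, pr)))
    mask = np.pad(mask, ((pt, pb), (pl, pr)))
    rec = ResizeRecord(original_size=(h, w), scale=scale, pad=(pt, pb, pl, pr), side=side)
    return Sample(image=image, mask=mask, id=sample.id), rec


def invert_letterbox(mask: np.ndarray, rec: ResizeRecord) -> np.ndarray:
    """Crop the letterbox padding and nearest-resize back to the native dims."""
    side = rec.side
    if mask.shape != (side, side):
        raise InputError(f"mask shape {mask.shape} inconsistent with record side {side}")
    pt, pb, pl, pr = rec.pad
    h, w = rec.original_size
    content = mask[pt:side - pb, pl:side - pr]
    if content.size == 0:
        raise InputError("resize record pads leave no content")
    return _resize_nearest(content, (h, w))


# ------------------------------------------------------------------------ augment
def _geom_resize_pair(image, mask, out_hw):
    return _resize_bilinear(image, out_hw), _resize_nearest(mask, out_hw)


def augment(sample: Sample, cfg: AugmentationConfig, rng: np.random.Generator) -> Sample:
    """Apply each configured transform independently with its probability.

    Geometric transforms act identically on image (bilinear) and mask
    (nearest); photometric transforms leave the mask untouched; the image
    is clipped to [0,1]; zero fill everywhere.
    """
    image = sample.image.astype(np.float32, copy=True)
    mask = sample.mask.copy()
    H, W = image.shape

    if rng.random() < cfg.p_brightness:
        image = image + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    if rng.random() < cfg.p_contrast:
        f = rng.uniform(*cfg.contrast_range)
        image = (image - image.mean()) * f + image.mean()
    if rng.random() < cfg.p_mirror:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if rng.random() < cfg.p_rotation:
        ang = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        image = ndimage.rotate(image, ang, reshape=False, order=1, cval=0.0)
        mask = ndimage.rotate(mask, ang, reshape=False, order=0, cval=0)
    if rng.random() < cfg.p_crop:
        kh = rng.uniform(cfg.crop_keep, 1.0)
        kw = rng.uniform(cfg.crop_keep, 1.0)
        ch, cw = max(int(round(H * kh)), 1), max(int(round(W * kw)), 1)
        y0 = rng.integers(0, H - ch + 1)
        x0 = rng.integers(0, W - cw + 1)
        image, mask = _geom_resize_pair(
            image[y0:y0 + ch, x0:x0 + cw], mask[y0:y0 + ch, x0:x0 + cw], (H, W)
        )
    if rng.random() < cfg.p_stretch:
        sy = rng.uniform(*cfg.stretch_range)
        sx = rng.uniform(*cfg.stretch_range)
        nh, nw = max(int(round(H * sy)), 1), max(int(round(W * sx)), 1)
        si, sm = _geom_resize_pair(image, mask, (nh, nw))
        # paste back onto an HxW zero canvas, centred (crop if larger)
        img2 = np.zeros((H, W), dtype=np.float32)
        msk2 = np.zeros((H, W), dtype=np.uint8)
        oy, ox = (H - nh) // 2, (W - nw) // 2
        sy0, sx0 = max(-oy, 0), max(-ox, 0)
        dy0, dx0 = max(oy, 0), max(ox, 0)
        hh, ww = min(nh - sy0, H - dy0), min(nw - sx0, W - dx0)
        img2[dy0:dy0 + hh, dx0:dx0 + ww] = si[sy0:sy0 + hh, sx0:sx0 + ww]
        msk2[dy0:dy0 + hh, dx0:dx0 + ww] = sm[sy0:sy0 + hh, sx0:sx0 + ww]
        image, mask = img2, msk2

    return Sample(image=np.clip(image, 0.0, 1.0), mask=mask, id=sample.id)
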