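"""Synthetic thyroid-ultrasound phantoms.

Each phantom is built mask-first: a two-lobe gland silhouette (two
ellipses joined by an isthmus, each with a smooth low-order Fourier
boundary perturbation), then nodules grown inside the gland support with
configurable boundary irregularity (low for benign-like, high for
malignant-like shapes).  The image is a per-region echogenicity map
(gland brighter than background, nodules offset hypo- or hyperechoic)
multiplied by gamma-distributed speckle with mean 1, optionally
attenuated by a smooth vertical acoustic-shadow band beneath a bright
arc, then Gaussian-blurred and clipped to [0, 1].

The speckle strength parameter is the multiplicative noise's standard
deviation sigma; the underlying gamma shape is 1/sigma**2 (mean fixed at
1), so larger strength means lower image SNR.

Everything is deterministic per seed; ``generate_dataset`` writes the
``data_io`` layout with byte-identical PNGs on regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import Sample, save_sample, write_manifest
from .exceptions import ConfigurationError, GenerationError


@dataclass
class PhantomConfig:
    side: int = 256
    # gland geometry (fractions of side)
    lobe_sep: float = 0.22  # half-distance between lobe centres
    lobe_ax: tuple[float, float] = (0.16, 0.24)  # (semi-axis x, semi-axis y)
    gland_jitter: float = 0.15  # relative jitter on centres/axes/orientation
    gland_wobble: float = 0.08  # Fourier boundary perturbation amplitude
    # nodules
    nodule_count: tuple[int, int] = (1, 3)
    nodule_radius: tuple[float, float] = (0.04, 0.12)  # fraction of side
    irregularity: float = 0.25  # boundary roughness amplitude (0 = smooth)
    nodule_offset: tuple[float, float] = (-0.35, -0.15)  # echogenicity offset range
    # intensities
    background_level: float = 0.25
    gland_level: float = 0.60
    # noise / artefacts
    speckle_strength: float = 0.25  # sigma of the mean-1 gamma speckle
    shadow_prob: float = 0.3
    shadow_width: tuple[float, float] = (0.08, 0.2)  # fraction of side
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.side < 32:
            raise ConfigurationError("side must be >= 32")
        if self.speckle_strength <= 0:
            raise ConfigurationError("speckle_strength must be positive")
        if self.nodule_count[0] < 0 or self.nodule_count[1] < self.nodule_count[0]:
            raise ConfigurationError("invalid nodule_count range")


def _wobbly_ellipse(
    side: int,
    cy: float,
    cx: float,
    ay: float,
    ax: float,
    angle: float,
    wobble: float,
    rng: np.random.Generator,
    modes: tuple[int, ...] = (2, 3, 4),
) -> np.ndarray:
    """Filled ellipse with a smooth random radial perturbation."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / ax
    v = (-sa * dx + ca * dy) / ay
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    boundary = np.ones_like(theta)
    for m in modes:
        amp = rng.uniform(-wobble, wobble)
        phase = rng.uniform(0, 2 * np.pi)
        boundary += amp * np.cos(m * theta + phase) / len(modes)
    return rho <= boundary


def _gland_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.side
    j = cfg.gland_jitter
    cy = s * (0.5 + rng.uniform(-j, j) * 0.3)
    sep = s * cfg.lobe_sep * (1 + rng.uniform(-j, j))
    mask = np.zeros((s, s), dtype=bool)
    for sign in (-1, 1):
        ax = s * cfg.lobe_ax[0] * (1 + rng.uniform(-j, j))
        ay = s * cfg.lobe_ax[1] * (1 + rng.uniform(-j, j))
        ang = rng.uniform(-0.25, 0.25)
        mask |= _wobbly_ellipse(
            s, cy + rng.uniform(-j, j) * s * 0.1, s * 0.5 + sign * sep, ay, ax, ang,
            cfg.gland_wobble, rng,
        )
    # isthmus bridging the lobes
    mask |= _wobbly_ellipse(s, cy, s * 0.5, s * 0.06, sep, 0.0, cfg.gland_wobble * 0.5, rng)
    return mask


def _place_nodules(
    cfg: PhantomConfig, gland: np.ndarray, rng: np.random.Generator, max_retries: int = 50
) -> list[np.ndarray]:
    s = cfg.side
    n = int(rng.integers(cfg.nodule_count[0], cfg.nodule_count[1] + 1))
    dist = ndimage.distance_transform_edt(gland)
    nodules = []
    for _ in range(n):
        placed = False
        for _ in range(max_retries):
            r = rng.uniform(*cfg.nodule_radius) * s
            ok = np.argwhere(dist >= 0.6 * r)
            if len(ok) == 0:
                continue
            cy, cx = ok[rng.integers(len(ok))]
            ecc = rng.uniform(0.7, 1.3)
            nod = _wobbly_ellipse(
                s, float(cy), float(cx), r * ecc, r / ecc, rng.uniform(0, np.pi),
                cfg.irregularity, rng,
            )
            nod &= gland  # nodules live inside the gland support
            if nod.sum() >= max(np.pi * (0.5 * r) ** 2, 4):
                nodules.append(nod)
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place a nodule of radius range {cfg.nodule_radius} "
                f"inside the gland after {max_retries} retries"
            )
    return nodules


def generate_phantom(
    cfg: PhantomConfig, seed: int | None = None, return_gland: bool = False
):
    """One synthetic image/mask pair; deterministic per seed.

    With ``return_gland=True`` also returns the boolean gland support the
    nodules were constrained to (useful for geometric assertions).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s = cfg.side

    gland = _gland_mask(cfg, rng)
    nodules = _place_nodules(cfg, gland, rng)
    mask = np.zeros((s, s), dtype=np.uint8)
    mask[gland] = 1
    for nod in nodules:
        mask[nod] = 2

    image = np.full((s, s), cfg.background_level, dtype=np.float32)
    image[gland] = cfg.gland_level
    for nod in nodules:
        image[nod] = cfg.gland_level + rng.uniform(*cfg.nodule_offset)

    # mean-1 gamma speckle: shape k = 1/sigma^2, scale sigma^2
    k = 1.0 / cfg.speckle_strength**2
    image = image * rng.gamma(k, 1.0 / k, size=(s, s)).astype(np.float32)

    if rng.random() < cfg.shadow_prob:
        width = rng.uniform(*cfg.shadow_width) * s
        col = rng.uniform(0.2, 0.8) * s
        top = rng.uniform(0.2, 0.6) * s
        xx = np.arange(s, dtype=np.float32)
        prof = np.exp(-0.5 * ((xx - col) / (width / 2)) ** 2)  # (W,)
        yy = np.arange(s, dtype=np.float32)[:, None]
        onset = 1.0 / (1.0 + np.exp(-(yy - top) / 3.0))  # smooth start below the arc
        atten = 1.0 - 0.6 * prof[None, :] * onset
        arc = 0.35 * prof[None, :] * np.exp(-0.5 * ((yy - top) / 2.5) ** 2)
        image = image * atten + arc

    if cfg.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, cfg.blur_sigma)
    sample = Sample(image=np.clip(image, 0.0, 1.0), mask=mask, id=f"phantom_{seed:06d}")
    return (sample, gland) if return_gland else sample


def generate_dataset(
    cfg: PhantomConfig,
    n: int,
    out_dir,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> list[dict]:
    """Write ``n`` phantoms in the data_io layout with a train/val/test manifest."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError("split fractions must sum to 1")
    out = Path(out_dir)
    samples = [generate_phantom(cfg, seed=cfg.seed + i) for i in range(n)]
    order = np.random.default_rng(cfg.seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[idx] = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
    rows = []
    for i, smp in enumerate(samples):
        save_sample(smp, out / "images", out / "masks")
        rows.append({"id": smp.id, "split": split_of[i]})
    write_manifest(rows, out / "manifest.csv")
    return rows


def radial_roughness(mask: np.ndarray, cls: int = 2) -> float:
    """Normalized boundary-radius spread of the largest ``cls`` component.

    The coefficient of variation of boundary-pixel distances from the
    component centroid: ~0 for a disk, larger for irregular shapes.
    """
    region = mask == cls
    if not region.any():
        return float("nan")
    lab, nlab = ndimage.label(region, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, nlab + 1))
    comp = lab == (1 + int(np.argmax(sizes)))
    eroded = ndimage.binary_erosion(comp)
    boundary = comp & ~eroded
    ys, xs = np.nonzero(boundary)
    cy, cx = ndimage.center_of_mass(comp)
    r = np.hypot(ys - cy, xs - cx)
    return float(r.std() / max(r.mean(), 1e-9))
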