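"""Training, evaluation and prediction.

Training follows the reference recipe: AdamW (lr 1e-4, weight decay 1e-2),
batch size 8, combined dice + weighted cross-entropy loss, Kaiming-
initialized weights, on-the-fly augmentation, and best-checkpoint
selection by the highest validation-set mean foreground dice after each
epoch.  A JSONL log records (epoch, train_loss, val_dice, lr).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from . import nn
from .analysis import keep_largest_component
from .data_io import AugmentationConfig, Sample, augment, invert_letterbox, letterbox
from .exceptions import ConfigurationError, InputError
from .losses import total_loss
from .metrics import MetricReport, evaluate_dataset
from .models import ModelConfig, SegmentationModel, build_model, load_model
from .nn.tensor import Tensor


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    val_fraction: float = 0.1
    seed: int = 0
    class_weights: tuple[float, ...] | None = None
    epsilon: float = 1.0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    checkpoint_dir: str = "checkpoints"
    log_path: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in (0,1)")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class CheckpointRecord:
    epoch: int
    val_mean_dice: float
    path: str
    config_hash: str
    history: list[dict] = field(default_factory=list)


def split_train_val(ids: list[str], val_fraction: float, seed: int) -> tuple[list[str], list[str]]:
    """Seeded shuffle-then-cut: the validation set is the first
    ceil(fraction * n) elements of the permutation, so validation sets are
    nested across growing fractions at a fixed seed."""
    if not ids:
        raise InputError("empty id list")
    n_val = int(np.ceil(val_fraction * len(ids)))
    if n_val < 1 or n_val >= len(ids):
        raise ConfigurationError(
            f"val_fraction {val_fraction} yields an empty train or val set for n={len(ids)}"
        )
    order = np.random.default_rng(seed).permutation(len(ids))
    val = [ids[i] for i in order[:n_val]]
    train = [ids[i] for i in order[n_val:]]
    return train, val


def _stack_batch(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, y


def _val_mean_dice(model: SegmentationModel, samples: list[Sample], batch_size: int) -> float:
    preds = []
    for i in range(0, len(samples), batch_size):
        x, _ = _stack_batch(samples[i:i + batch_size])
        preds.extend(model.predict_classes(x))
    report = evaluate_dataset(preds, [s.mask for s in samples],
                              num_classes=model.cfg.num_classes)
    return report.mean["Dice"]


def _config_hash(cfg: TrainConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]


def train(cfg: TrainConfig, samples: list[Sample]) -> CheckpointRecord:
    """Train on ``samples`` (internally split train/val) and return the
    best-validation-dice checkpoint record with the full epoch history."""
    if not samples:
        raise InputError("empty dataset")
    ids = [s.id for s in samples]
    by_id = {s.id: s for s in samples}
    train_ids, val_ids = split_train_val(ids, cfg.val_fraction, cfg.seed)
    train_set = [by_id[i] for i in train_ids]
    val_set = [by_id[i] for i in val_ids]

    model = build_model(cfg.model)
    opt = nn.AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    ckpt_dir = Path(cfg.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    best_path = ckpt_dir / f"best_{cfg.model.variant}_{chash}.npz"

    history: list[dict] = []
    best = CheckpointRecord(epoch=-1, val_mean_dice=-1.0, path=str(best_path),
                            config_hash=chash, history=history)
    log_f = open(cfg.log_path, "w") if cfg.log_path else None
    try:
        for epoch in range(cfg.epochs):
            rng = np.random.default_rng([cfg.seed, epoch])
            order = rng.permutation(len(train_set))
            model.train()
            losses = []
            for bstart in range(0, len(order), cfg.batch_size):
                batch = [train_set[i] for i in order[bstart:bstart + cfg.batch_size]]
                batch = [augment(s, cfg.augmentation, rng) for s in batch]
                x, y = _stack_batch(batch)
                logits = model(Tensor(x))
                loss = total_loss(logits, y, cfg.class_weights, cfg.epsilon)
                lv = float(loss.total.data)
                if not np.isfinite(lv):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {bstart // cfg.batch_size}: "
                        f"wce={float(loss.wce.data)}, dice={float(loss.dice.data)}"
                    )
                opt.zero_grad()
                loss.total.backward()
                opt.step()
                losses.append(lv)
            val_dice = _val_mean_dice(model, val_set, cfg.batch_size)
            entry = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_dice": float(val_dice),
                "lr": cfg.learning_rate,
            }
            history.append(entry)
            if log_f:
                log_f.write(json.dumps(entry) + "\n")
                log_f.flush()
            if val_dice > best.val_mean_dice:
                best.val_mean_dice = float(val_dice)
                best.epoch = epoch
                model.save(best_path)
    finally:
        if log_f:
            log_f.close()
    return best


def evaluate(
    checkpoint, samples: list[Sample], out_dir=None, averaging: str = "macro",
    batch_size: int = 8,
) -> MetricReport:
    """Evaluation-mode forward + argmax on every sample, then metrics.

    ``checkpoint`` may be a path to a saved model or a live model.
    """
    model = checkpoint if isinstance(checkpoint, SegmentationModel) else load_model(checkpoint)
    if not samples:
        raise InputError("empty dataset")
    preds = []
    for i in range(0, len(samples), batch_size):
        x, _ = _stack_batch(samples[i:i + batch_size])
        preds.extend(model.predict_classes(x))
    report = evaluate_dataset(
        preds, [s.mask for s in samples], num_classes=model.cfg.num_classes,
        averaging=averaging, image_ids=[s.id for s in samples],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "per_image_metrics.csv")
        report.to_json(out / "summary.json")
    return report


# -------------------------------------------------------------------- prediction
GLAND_COLOR = (30, 80, 255)  # blue outline
NODULE_COLOR = (255, 40, 40)  # red outline


def _boundaries(mask: np.ndarray, cls: int) -> np.ndarray:
    region = mask == cls
    return region & ~ndimage.binary_erosion(region, border_value=0)


def overlay_contours(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gland contours in blue, nodule contours in red on the grayscale image."""
    rgb = np.repeat((np.clip(image, 0, 1) * 255).astype(np.uint8)[..., None], 3, axis=2)
    for cls, color in ((1, GLAND_COLOR), (2, NODULE_COLOR)):
        rgb[_boundaries(mask, cls)] = color
    return rgb


def predict(
    checkpoint,
    image_path,
    out_mask_path=None,
    out_overlay_path=None,
    side: int = 512,
    postprocess: bool = True,
    min_area: int | None = None,
) -> np.ndarray:
    """Letterbox -> forward -> argmax -> optional component filter ->
    inverse letterbox; writes the native-resolution mask and a contour
    overlay when paths are given."""
    model = checkpoint if isinstance(checkpoint, SegmentationModel) else load_model(checkpoint)
    img = np.asarray(Image.open(image_path))
    if img.ndim == 3:
        img = img.mean(axis=2)
    image = img.astype(np.float32) / 255.0 if img.dtype == np.uint8 else img.astype(np.float32)
    sample = Sample(image=image, mask=np.zeros_like(image, dtype=np.uint8), id=Path(image_path).stem)
    boxed, rec = letterbox(sample, side=side)
    pred = model.predict_classes(boxed.image[None, None])[0]
    if postprocess:
        for cls in (1, 2):
            pred = keep_largest_component(pred, cls, min_area=min_area)
    native = invert_letterbox(pred, rec)
    if out_mask_path:
        Image.fromarray(native.astype(np.uint8), mode="L").save(out_mask_path)
    if out_overlay_path:
        Image.fromarray(overlay_contours(image, native), mode="RGB").save(out_overlay_path)
    return native
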