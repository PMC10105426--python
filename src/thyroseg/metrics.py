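"""Segmentation assessment criteria.

Per class (one-vs-rest pixel counts TP/FP/TN/FN):

    SP  = TN / (TN + FP)            SE  = TP / (TP + FN)
    PR  = TP / (TP + FP)            ACC = (TP + TN) / total
    IoU = TP / (TP + FP + FN)       Dice = 2 TP / (2 TP + FP + FN)

Degenerate-denominator convention: a class absent from both truth and
prediction scores 1.0 for the affected ratios (there is nothing to get
wrong); an absent class that *was* predicted scores 0.0 through the
ordinary formula.  Mean metrics default to a macro average over images
and over the foreground classes (gland, nodule); the background class is
reported per class but excluded from the mean unless requested.  Micro
averaging (pool the counts, then compute) is also available.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

METRIC_NAMES = ("SP", "SE", "PR", "ACC", "IoU", "Dice")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_counts(pred, truth, cls: int) -> ConfusionCounts:
    """One-vs-rest pixel counts for class ``cls``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == cls
    t = truth == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 1.0


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The six criteria from one set of counts (degenerate convention above)."""
    return {
        "SP": _ratio(c.tn, c.tn + c.fp),
        "SE": _ratio(c.tp, c.tp + c.fn),
        "PR": _ratio(c.tp, c.tp + c.fp),
        "ACC": _ratio(c.tp + c.tn, c.total),
        "IoU": _ratio(c.tp, c.tp + c.fp + c.fn),
        "Dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


@dataclass
class MetricReport:
    per_class: dict[int, dict[str, float]]  # class -> metric -> mean over images
    mean: dict[str, float]  # averaged over ``mean_classes``
    nodule_dice: float
    per_image: list[dict] = field(default_factory=list)  # rows: image, class, metrics
    averaging: str = "macro"
    mean_classes: tuple[int, ...] = (1, 2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            wr = csv.writer(f)
            wr.writerow(["image", "class", *METRIC_NAMES])
            for row in self.per_image:
                wr.writerow([row["image"], row["class"], *(row[m] for m in METRIC_NAMES)])

    def summary(self) -> dict[str, float]:
        """Table-style summary in percent."""
        out = {f"{m} (%)": 100.0 * self.mean[m] for m in METRIC_NAMES}
        out["Nodule dice (%)"] = 100.0 * self.nodule_dice
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=2)


def evaluate_dataset(
    preds,
    truths,
    num_classes: int = 3,
    averaging: str = "macro",
    mean_classes: tuple[int, ...] = (1, 2),
    image_ids=None,
) -> MetricReport:
    """Per-class and mean metrics over a dataset of mask pairs.

    macro: compute per image per class, average over images, then over
    ``mean_classes``.  micro: pool the confusion counts over images first.
    """
    preds = list(preds)
    truths = list(truths)
    if len(preds) == 0 or len(preds) != len(truths):
        raise InputError("need equal, nonempty prediction/truth lists")
    if averaging not in ("macro", "micro"):
        raise InputError(f"averaging must be macro or micro, got {averaging!r}")
    ids = image_ids or [str(i) for i in range(len(preds))]

    per_image = []
    pooled = {c: ConfusionCounts(0, 0, 0, 0) for c in range(num_classes)}
    acc: dict[int, dict[str, list[float]]] = {
        c: {m: [] for m in METRIC_NAMES} for c in range(num_classes)
    }
    for img_id, p, t in zip(ids, preds, truths):
        for c in range(num_classes):
            counts = confusion_counts(p, t, c)
            pooled[c] = pooled[c] + counts
            m = compute_metrics(counts)
            per_image.append({"image": img_id, "class": c, **m})
            for name, v in m.items():
                acc[c][name].append(v)

    if averaging == "macro":
        per_class = {
            c: {m: float(np.mean(acc[c][m])) for m in METRIC_NAMES} for c in range(num_classes)
        }
    else:
        per_class = {c: compute_metrics(pooled[c]) for c in range(num_classes)}

    mean = {
        m: float(np.mean([per_class[c][m] for c in mean_classes])) for m in METRIC_NAMES
    }
    nodule_dice = per_class[2]["Dice"] if num_classes > 2 else float("nan")
    return MetricReport(
        per_class=per_class,
        mean=mean,
        nodule_dice=nodule_dice,
        per_image=per_image,
        averaging=averaging,
        mean_classes=tuple(mean_classes),
    )
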