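"""Training losses (BCE + Dice) and the six-metric evaluation suite.

The training loss is ``L = lambda * BCE + Dice``: pixelwise binary
cross-entropy with mean reduction (so the magnitude is independent of image
resolution) plus the soft Dice overlap loss ``1 - 2*sum(f*g) /
(sum(f) + sum(g))``. Evaluation thresholds the probability map at 0.5,
accumulates pixel confusion counts, and reports accuracy, recall, precision,
specificity, F1 and IoU; mIoU is the mean of the foreground and background
IoU computed from the same counts.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "f1", "iou")

# column order used by the evaluation report
REPORT_COLUMNS = ("Accuracy", "Recall", "Specificity", "Precision", "mIoU", "F1")


@dataclass
class LossConfig:
    """``bce_weight`` is the scalar weighting the BCE term; ``eps`` clips
    probabilities away from {0, 1} before the logarithm."""

    bce_weight: float = 1.0
    eps: float = 1e-7

    def __post_init__(self):
        if self.bce_weight < 0:
            raise ValueError(f"bce_weight must be >= 0, got {self.bce_weight}")
        if not 0 < self.eps < 0.5:
            raise ValueError(f"eps must be in (0, 0.5), got {self.eps}")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def _check_binary(g):
    gd = g.data if isinstance(g, Tensor) else np.asarray(g)
    if not np.isin(gd, (0, 1)).all():
        raise ValueError("ground-truth map must be binary {0, 1}")
    return gd


def bce_loss(f, g, cfg=None):
    """Mean binary cross-entropy between probabilities ``f`` and labels ``g``."""
    cfg = cfg or LossConfig()
    gd = _check_binary(g)
    if not isinstance(f, Tensor):
        f = Tensor(f)
    if f.shape != gd.shape:
        raise ValueError(f"shape mismatch: prediction {f.shape} vs target {gd.shape}")
    fc = f.clip(cfg.eps, 1.0 - cfg.eps)
    gd = gd.astype(fc.data.dtype)
    ll = Tensor(gd) * fc.log() + Tensor(1.0 - gd) * (1.0 - fc).log()
    return -ll.mean()


def dice_loss(f, g, guard=1e-7):
    """Soft Dice loss ``1 - 2*sum(f*g)/(sum(f)+sum(g))``, in [0, 1].

    Both maps identically zero is a degenerate perfect match; returns 0 with
    a warning rather than 1 from the guarded denominator.
    """
    if not isinstance(f, Tensor):
        f = Tensor(f)
    g_t = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=f.data.dtype))
    if f.shape != g_t.shape:
        raise ValueError(f"shape mismatch: prediction {f.shape} vs target {g_t.shape}")
    denom = float(f.data.sum() + g_t.data.sum())
    if denom == 0.0:
        warnings.warn("dice_loss: both maps empty; returning 0 by convention")
        return f.sum() * 0.0
    inter = (f * g_t).sum()
    return 1.0 - 2.0 * inter / (f.sum() + g_t.sum() + guard)


def combined_loss(f, g, cfg=None):
    """``lambda * BCE + Dice`` (the full training objective)."""
    cfg = cfg or LossConfig()
    return bce_loss(f, g, cfg) * cfg.bce_weight + dice_loss(f, g)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion_counts(f, g, threshold=0.5):
    """Pixel confusion counts of ``f >= threshold`` against binary ``g``."""
    fd = f.data if isinstance(f, Tensor) else np.asarray(f)
    gd = _check_binary(g).astype(bool)
    if fd.shape != gd.shape:
        raise ValueError(f"shape mismatch: prediction {fd.shape} vs target {gd.shape}")
    pred = fd >= threshold
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & gd)),
        tn=int(np.count_nonzero(~pred & ~gd)),
        fp=int(np.count_nonzero(pred & ~gd)),
        fn=int(np.count_nonzero(~pred & gd)),
    )


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name}: zero denominator; reporting NaN")
        return math.nan
    return num / den


def segmentation_metrics(c):
    """Accuracy, recall, precision, specificity, F1 and IoU from counts."""
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    rec = _ratio(c.tp, c.tp + c.fn, "recall")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    if math.isnan(rec) or math.isnan(prec) or (prec + rec) == 0:
        warnings.warn("f1: undefined (no positive predictions or labels)")
        f1 = math.nan
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, "iou")
    return {
        "accuracy": acc,
        "recall": rec,
        "precision": prec,
        "specificity": spec,
        "f1": f1,
        "iou": iou,
    }


def two_class_ious(c):
    """(foreground IoU, background IoU) from one set of counts."""
    fg = _ratio(c.tp, c.tp + c.fp + c.fn, "foreground iou")
    bg = _ratio(c.tn, c.tn + c.fp + c.fn, "background iou")
    return fg, bg


def mean_iou(per_class_ious):
    """Arithmetic mean of per-class IoU values."""
    ious = list(per_class_ious)
    if not ious:
        raise ValueError("mean_iou: empty list")
    return float(np.mean(ious))


def evaluate_dataset(counts_list):
    """Aggregate per-image counts and report the six metrics plus mIoU."""
    total = ConfusionCounts(0, 0, 0, 0)
    for c in counts_list:
        total = total + c
    m = segmentation_metrics(total)
    m["miou"] = mean_iou(two_class_ious(total))
    return m, total


def metrics_table(rows):
    """Render metric dicts as a delimited table of percentages (2 decimals).

    ``rows`` maps a split name to a metrics dict as produced by
    :func:`evaluate_dataset`. Column order: Accuracy, Recall, Specificity,
    Precision, mIoU, F1.
    """
    key = {
        "Accuracy": "accuracy",
        "Recall": "recall",
        "Specificity": "specificity",
        "Precision": "precision",
        "mIoU": "miou",
        "F1": "f1",
    }
    buf = io.StringIO()
    buf.write("Split," + ",".join(REPORT_COLUMNS) + "\n")
    for name, m in rows.items():
        cells = [f"{100.0 * m[key[col]]:.2f}" for col in REPORT_COLUMNS]
        buf.write(name + "," + ",".join(cells) + "\n")
    return buf.getvalue()
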