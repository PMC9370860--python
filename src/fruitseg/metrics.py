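"""Pixel-wise segmentation evaluation.

Fruit is the positive class. With TP/TN/FP/FN per-pixel counts:

    P  = TP / (TP + FP)
    R  = TP / (FN + TP)
    F1 = 2 P R / (P + R)
    IoU(class) = TP_c / (TP_c + FP_c + FN_c)

Global accuracy is the fraction of correctly classified pixels regardless
of class; mean accuracy averages the per-class correct fractions; mean
IoU averages the two class IoUs; weighted IoU weights each class IoU by
its ground-truth pixel share.  Metrics are computed per image and then
arithmetically averaged over the test set (aggregate-pixel versions are
also reported).

Degenerate-count conventions: if TP = FP = FN = 0 (both masks empty) the
prediction is perfect, so P = R = F1 = fruit IoU = 1; if TP = 0 but
FP > 0 or FN > 0, the undefined member of {P, R} is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .samples import LabeledSample, as_binary_mask

ERROR_MAP_COLORS = {
    "tp": (255, 255, 255),  # white
    "tn": (0, 0, 0),        # black
    "fn": (255, 0, 255),    # magenta
    "fp": (0, 255, 0),      # green
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel tally; fruit (mask value 1) is the positive class."""
    pred = as_binary_mask(pred)
    gt = as_binary_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.fn + c.tp) if (c.fn + c.tp) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def _class_iou(tp: int, fp: int, fn: int) -> float:
    denom = tp + fp + fn
    return tp / denom if denom else 1.0


def iou_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(mean IoU, weighted IoU) over the two classes.

    Background counts follow by symmetry: its TP is the fruit TN, its
    FP the fruit FN, and vice versa. The weighted variant weights each
    class IoU by the class's ground-truth pixel share.
    """
    iou_fruit = _class_iou(c.tp, c.fp, c.fn)
    iou_bg = _class_iou(c.tn, c.fn, c.fp)
    mean_iou = (iou_fruit + iou_bg) / 2.0
    total = c.total
    share_fruit = (c.tp + c.fn) / total if total else 0.5
    weighted_iou = share_fruit * iou_fruit + (1.0 - share_fruit) * iou_bg
    return mean_iou, weighted_iou


def accuracy_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(global accuracy, mean accuracy).

    Global: correct pixels over all pixels. Mean: average of per-class
    correct fractions (per-class recall); an absent class counts as
    perfectly classified.
    """
    total = c.total
    global_acc = (c.tp + c.tn) / total if total else 1.0
    acc_fruit = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0
    acc_bg = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 1.0
    return global_acc, (acc_fruit + acc_bg) / 2.0


def image_metrics(pred: np.ndarray, gt: np.ndarray) -> dict:
    """All per-image metrics as a flat dict of fractions in [0, 1]."""
    c = confusion_counts(pred, gt)
    p, r, f1 = precision_recall_f1(c)
    mean_iou, weighted_iou = iou_metrics(c)
    global_acc, mean_acc = accuracy_metrics(c)
    return {
        "precision": p,
        "recall": r,
        "f1": f1,
        "global_accuracy": global_acc,
        "mean_accuracy": mean_acc,
        "mean_iou": mean_iou,
        "weighted_iou": weighted_iou,
        "tp": c.tp,
        "tn": c.tn,
        "fp": c.fp,
        "fn": c.fn,
    }


_METRIC_KEYS = (
    "precision",
    "recall",
    "f1",
    "global_accuracy",
    "mean_accuracy",
    "mean_iou",
    "weighted_iou",
)


@dataclass
class MetricsReport:
    """Per-image rows plus their arithmetic averages.

    Averaged metrics are fractions in [0, 1]; ``as_percentages`` rescales
    them for reporting. ``aggregate`` holds the same metrics recomputed
    from the summed pixel counts, and ``aggregate_confusion`` the summed
    counts themselves.
    """

    per_image: list[dict]
    averages: dict
    aggregate: dict
    aggregate_confusion: ConfusionCounts
    model_tag: str = ""

    def as_percentages(self) -> dict:
        return {k: 100.0 * self.averages[k] for k in _METRIC_KEYS}


def evaluate_predictions(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    model_tag: str = "",
    sample_ids: Sequence[str] | None = None,
) -> MetricsReport:
    """Score prediction/ground-truth mask pairs (per-image averaging)."""
    if len(preds) == 0 or len(preds) != len(gts):
        raise ValueError("need equal, non-empty prediction and ground-truth lists")
    rows = []
    agg = ConfusionCounts(0, 0, 0, 0)
    for i, (p, g) in enumerate(zip(preds, gts)):
        row = image_metrics(p, g)
        row["sample_id"] = sample_ids[i] if sample_ids else str(i)
        rows.append(row)
        agg = agg + ConfusionCounts(row["tp"], row["tn"], row["fp"], row["fn"])
    averages = {k: float(np.mean([r[k] for r in rows])) for k in _METRIC_KEYS}
    pa, ra, f1a = precision_recall_f1(agg)
    miou_a, wiou_a = iou_metrics(agg)
    ga, ma = accuracy_metrics(agg)
    aggregate = {
        "precision": pa,
        "recall": ra,
        "f1": f1a,
        "global_accuracy": ga,
        "mean_accuracy": ma,
        "mean_iou": miou_a,
        "weighted_iou": wiou_a,
    }
    return MetricsReport(
        per_image=rows,
        averages=averages,
        aggregate=aggregate,
        aggregate_confusion=agg,
        model_tag=model_tag,
    )


def evaluate_test_set(model, test: Sequence[LabeledSample]) -> MetricsReport:
    """Run a trained model over a labeled test set and score it."""
    from .segnet import predict_mask

    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    preds = [predict_mask(model, s.image) for s in test]
    gts = [s.mask for s in test]
    return evaluate_predictions(
        preds, gts, model_tag=model.stage_tag, sample_ids=[s.sample_id for s in test]
    )


def error_map(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Four-color per-pixel error visualization.

    TP white, TN black, FN magenta, FP green.
    """
    pred = as_binary_mask(pred)
    gt = as_binary_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    p = pred.astype(bool)
    g = gt.astype(bool)
    out[p & g] = ERROR_MAP_COLORS["tp"]
    out[~p & ~g] = ERROR_MAP_COLORS["tn"]
    out[~p & g] = ERROR_MAP_COLORS["fn"]
    out[p & ~g] = ERROR_MAP_COLORS["fp"]
    return out


def report_to_csv(report: MetricsReport) -> str:
    """Per-image rows plus an AVERAGE row, as CSV text."""
    cols = ["sample_id", *(_METRIC_KEYS), "tp", "tn", "fp", "fn"]
    lines = [",".join(cols)]
    for r in report.per_image:
        lines.append(",".join(str(r[c]) for c in cols))
    avg = report.averages
    lines.append(
        ",".join(
            ["AVERAGE"]
            + [f"{avg[k]:.6f}" for k in _METRIC_KEYS]
            + [
                str(report.aggregate_confusion.tp),
                str(report.aggregate_confusion.tn),
                str(report.aggregate_confusion.fp),
                str(report.aggregate_confusion.fn),
            ]
        )
    )
    return "\n".join(lines) + "\n"
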