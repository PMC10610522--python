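"""Segmentation metrics and the before/after-correction comparison harness.

Conventions (documented because they matter when comparing numbers):

* Dice = 2|A∩B| / (|A|+|B|), IoU = |A∩B| / |A∪B|; both defined as 1.0 when
  prediction and reference are both empty, so frames where a chamber is
  legitimately absent from both are not dropped.
* Per-class pixel accuracy is the recall of that class (correct class-c
  pixels / reference class-c pixels); mean pixel accuracy averages the
  per-class values over the classes present in the reference.
* Multi-frame numbers are macro averages: the metric is computed per frame
  and then averaged over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "dice",
    "iou",
    "pixel_accuracy",
    "per_class_pixel_accuracy",
    "mean_pixel_accuracy",
    "labelmap_metrics",
    "MetricsReport",
    "ComparisonTable",
    "compare_correction",
]

FOREGROUND_CLASSES = (1, 2, 3, 4)


def _binary_pair(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"size mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def dice(pred_mask, gt_mask) -> float:
    """Dice coefficient of two binary masks (1.0 for two empty masks)."""
    a, b = _binary_pair(pred_mask, gt_mask)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(pred_mask, gt_mask) -> float:
    """Jaccard index of two binary masks (1.0 for two empty masks)."""
    a, b = _binary_pair(pred_mask, gt_mask)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def pixel_accuracy(pred, gt) -> float:
    """Fraction of pixels whose predicted class equals the reference."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"size mismatch: {pred.shape} vs {gt.shape}")
    return float((pred == gt).mean())


def per_class_pixel_accuracy(pred, gt, class_id) -> float | None:
    """Recall of one class; None when the class is absent from ``gt``."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"size mismatch: {pred.shape} vs {gt.shape}")
    m = gt == class_id
    n = int(m.sum())
    if n == 0:
        return None
    return int((pred[m] == class_id).sum()) / n


def mean_pixel_accuracy(pred, gt, classes=(0,) + FOREGROUND_CLASSES) -> float:
    """Mean of per-class recalls over the classes present in ``gt``."""
    vals = [per_class_pixel_accuracy(pred, gt, c) for c in classes]
    vals = [v for v in vals if v is not None]
    if not vals:
        raise ValueError("no requested class present in the reference map")
    return float(np.mean(vals))


def labelmap_metrics(pred, gt, classes=FOREGROUND_CLASSES) -> dict:
    """Macro Dice/IoU over chamber classes plus accuracy for one frame."""
    d = [dice(np.asarray(pred) == c, np.asarray(gt) == c) for c in classes]
    j = [iou(np.asarray(pred) == c, np.asarray(gt) == c) for c in classes]
    return {
        "dice": float(np.mean(d)),
        "iou": float(np.mean(j)),
        "mean_pixel_accuracy": mean_pixel_accuracy(pred, gt),
        "pixel_accuracy": pixel_accuracy(pred, gt),
    }


@dataclass
class MetricsReport:
    """Macro metrics over a set of frames.

    ``dice``/``iou`` are macro averages over chamber classes and frames;
    per-class entries are averaged over the frames where the class is
    present in the reference.
    """

    dice: float
    iou: float
    mean_pixel_accuracy: float
    per_class_dice: dict
    per_class_iou: dict
    per_class_pixel_accuracy: dict
    n_items: int

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "iou": self.iou,
            "mean_pixel_accuracy": self.mean_pixel_accuracy,
            "per_class_dice": self.per_class_dice,
            "per_class_iou": self.per_class_iou,
            "per_class_pixel_accuracy": self.per_class_pixel_accuracy,
            "n_items": self.n_items,
            "averaging": "per-frame macro",
        }

    @classmethod
    def from_pairs(cls, preds, gts, classes=FOREGROUND_CLASSES) -> "MetricsReport":
        preds, gts = list(preds), list(gts)
        if len(preds) != len(gts):
            raise ValueError("prediction and reference counts differ")
        if not preds:
            raise ValueError("empty evaluation set")
        frame_dice, frame_iou, frame_mpa = [], [], []
        pc_dice = {c: [] for c in classes}
        pc_iou = {c: [] for c in classes}
        pc_acc = {c: [] for c in classes}
        for p, g in zip(preds, gts):
            p, g = np.asarray(p), np.asarray(g)
            ds, js = [], []
            for c in classes:
                dc = dice(p == c, g == c)
                jc = iou(p == c, g == c)
                ds.append(dc)
                js.append(jc)
                pc_dice[c].append(dc)
                pc_iou[c].append(jc)
                acc = per_class_pixel_accuracy(p, g, c)
                if acc is not None:
                    pc_acc[c].append(acc)
            frame_dice.append(np.mean(ds))
            frame_iou.append(np.mean(js))
            frame_mpa.append(mean_pixel_accuracy(p, g))
        return cls(
            dice=float(np.mean(frame_dice)),
            iou=float(np.mean(frame_iou)),
            mean_pixel_accuracy=float(np.mean(frame_mpa)),
            per_class_dice={c: float(np.mean(v)) for c, v in pc_dice.items()},
            per_class_iou={c: float(np.mean(v)) for c, v in pc_iou.items()},
            per_class_pixel_accuracy={
                c: (float(np.mean(v)) if v else None) for c, v in pc_acc.items()
            },
            n_items=len(preds),
        )


@dataclass
class ComparisonTable:
    """Per-chamber Dice before/after correction, full set and flagged subset."""

    rows: list = field(default_factory=list)  # dicts per chamber

    def to_dict(self) -> dict:
        return {"rows": self.rows}

    def to_csv(self) -> str:
        header = (
            "chamber,dice_original_all,dice_corrected_all,difference_all,"
            "dice_original_flagged,dice_corrected_flagged,difference_flagged"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                "{chamber},{dice_original_all:.4f},{dice_corrected_all:.4f},"
                "{difference_all:.4f},{dice_original_flagged},"
                "{dice_corrected_flagged},{difference_flagged}".format(
                    **{
                        k: (f"{v:.4f}" if isinstance(v, float) else v)
                        for k, v in r.items()
                    }
                )
            )
        return "\n".join(lines) + "\n"


CHAMBER_NAMES = {
    1: "left_ventricle",
    2: "left_atrium",
    3: "right_ventricle",
    4: "right_atrium",
}


def compare_correction(preds, corrected, gts, flagged_subset=()) -> ComparisonTable:
    """Per-chamber macro Dice of original vs corrected predictions.

    ``flagged_subset`` holds indices of frames marked as needing
    correction; their averages are reported alongside the full set.
    """
    preds, corrected, gts = list(preds), list(corrected), list(gts)
    if not (len(preds) == len(corrected) == len(gts)):
        raise ValueError("prediction, corrected and reference counts differ")
    flagged = set(flagged_subset)
    if flagged and not flagged.issubset(range(len(preds))):
        raise ValueError("flagged_subset contains out-of-range indices")
    table = ComparisonTable()
    for c in FOREGROUND_CLASSES:
        orig_all, corr_all, orig_fl, corr_fl = [], [], [], []
        for i, (p, q, g) in enumerate(zip(preds, corrected, gts)):
            p, q, g = np.asarray(p), np.asarray(q), np.asarray(g)
            do = dice(p == c, g == c)
            dc = dice(q == c, g == c)
            orig_all.append(do)
            corr_all.append(dc)
            if i in flagged:
                orig_fl.append(do)
                corr_fl.append(dc)
        row = {
            "chamber": CHAMBER_NAMES[c],
            "dice_original_all": float(np.mean(orig_all)),
            "dice_corrected_all": float(np.mean(corr_all)),
        }
        row["difference_all"] = row["dice_corrected_all"] - row["dice_original_all"]
        if orig_fl:
            row["dice_original_flagged"] = float(np.mean(orig_fl))
            row["dice_corrected_flagged"] = float(np.mean(corr_fl))
            row["difference_flagged"] = (
                row["dice_corrected_flagged"] - row["dice_original_flagged"]
            )
        else:
            row["dice_original_flagged"] = None
            row["dice_corrected_flagged"] = None
            row["difference_flagged"] = None
        table.rows.append(row)
    return table
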