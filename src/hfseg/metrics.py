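"""Per-class Dice and IoU with class-averaged means.

For each class c, A is the set of reference pixels labelled c and B the
set of predicted pixels labelled c:

    Dice = 2|A∩B| / (|A| + |B|)        IoU = |A∩B| / |A∪B|

mDice / mIoU average over an evaluated class set — by default the
foreground classes only, mirroring evaluations that report per-structure
scores plus their mean.  A class empty in both masks scores 1.0 for both
metrics (nothing to find, nothing found) and is included in the mean;
both conventions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClassCounts:
    gt: int            # |A|
    pred: int          # |B|
    intersection: int  # |A ∩ B|

    @property
    def union(self) -> int:
        return self.gt + self.pred - self.intersection


@dataclass
class MetricsReport:
    dice: dict[int, float] = field(default_factory=dict)
    iou: dict[int, float] = field(default_factory=dict)
    counts: dict[int, ClassCounts] = field(default_factory=dict)
    mdice: float = float("nan")
    miou: float = float("nan")

    def to_rows(self) -> list[dict]:
        rows = [{"class": c, "dice": self.dice[c], "iou": self.iou[c],
                 "gt_pixels": self.counts[c].gt, "pred_pixels": self.counts[c].pred,
                 "intersection": self.counts[c].intersection}
                for c in sorted(self.dice)]
        rows.append({"class": "mean", "dice": self.mdice, "iou": self.miou,
                     "gt_pixels": "", "pred_pixels": "", "intersection": ""})
        return rows

    def to_text(self) -> str:
        lines = ["class\tdice\tiou\tgt_pixels\tpred_pixels\tintersection"]
        for r in self.to_rows():
            lines.append("\t".join(str(r[k]) for k in
                                   ("class", "dice", "iou", "gt_pixels",
                                    "pred_pixels", "intersection")))
        return "\n".join(lines)


def dice_iou(pred: np.ndarray, gt: np.ndarray,
             class_set=None, num_classes: int | None = None,
             include_background: bool = False,
             empty_score: float = 1.0) -> MetricsReport:
    """Overlap metrics between an integer prediction mask and a reference mask.

    `class_set` defaults to the foreground classes (1..C-1) where C is
    `num_classes` or the largest label present plus one; pass
    `include_background=True` to fold class 0 into the mean.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if class_set is None:
        c = num_classes if num_classes is not None else int(max(pred.max(), gt.max())) + 1
        class_set = range(0 if include_background else 1, c)
    report = MetricsReport()
    for c in class_set:
        a = gt == c
        b = pred == c
        inter = int(np.count_nonzero(a & b))
        na, nb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
        report.counts[c] = ClassCounts(gt=na, pred=nb, intersection=inter)
        if na + nb == 0:
            report.dice[c] = empty_score
            report.iou[c] = empty_score
        else:
            report.dice[c] = 2.0 * inter / (na + nb)
            report.iou[c] = inter / (na + nb - inter)
    if report.dice:
        report.mdice = float(np.mean(list(report.dice.values())))
        report.miou = float(np.mean(list(report.iou.values())))
    return report


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Per-image metrics averaged over an evaluation set (macro average)."""
    if not reports:
        raise ValueError("no reports to average")
    classes = sorted(reports[0].dice)
    out = MetricsReport()
    for c in classes:
        out.dice[c] = float(np.mean([r.dice[c] for r in reports]))
        out.iou[c] = float(np.mean([r.iou[c] for r in reports]))
        out.counts[c] = ClassCounts(
            gt=sum(r.counts[c].gt for r in reports),
            pred=sum(r.counts[c].pred for r in reports),
            intersection=sum(r.counts[c].intersection for r in reports))
    out.mdice = float(np.mean([r.mdice for r in reports]))
    out.miou = float(np.mean([r.miou for r in reports]))
    return out
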