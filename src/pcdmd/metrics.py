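"""Evaluation suite: CNR, mean IoU, mean Dice, R-squared, report assembly.

CNR uses the population standard deviation of the background ROI
(|ROI mean - background mean| / background SD).  mIoU and mDSC average over
the configured class set (default: background + the three materials); a class
absent from both maps scores 1 (empty-set convention, recorded in the
report).  R-squared is pooled over all material channels and pixels.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

import numpy as np

from .phantom import CLASS_NAMES

__all__ = ["RoiSet", "MetricsReport", "cnr", "miou", "mdsc", "r2_score", "evaluate", "roi_mask"]

DEFAULT_CLASSES = tuple(range(len(CLASS_NAMES)))


@dataclass(frozen=True)
class CircularRoi:
    center: tuple  # (x, y) mm
    radius: float  # mm
    label: str = ""


@dataclass(frozen=True)
class RoiSet:
    rois: tuple
    background: CircularRoi

    def __post_init__(self):
        for r in self.rois:
            d = np.hypot(r.center[0] - self.background.center[0],
                         r.center[1] - self.background.center[1])
            if d < r.radius + self.background.radius:
                raise ValueError("background ROI must be disjoint from insert ROIs")


def roi_mask(shape: tuple, pitch_mm: float, roi: CircularRoi) -> np.ndarray:
    n = shape[-1]
    c = (np.arange(n) - n // 2) * pitch_mm
    xx, yy = np.meshgrid(c, c)
    return (xx - roi.center[0]) ** 2 + (yy - roi.center[1]) ** 2 <= roi.radius**2


def cnr(image: np.ndarray, roi: np.ndarray, background_roi: np.ndarray) -> float:
    """|mean(ROI) - mean(background)| / SD(background), population SD."""
    bg = image[background_roi]
    sd = float(bg.std(ddof=0))
    if sd == 0:
        raise ValueError("undefined CNR: background SD is zero")
    return float(abs(image[roi].mean() - bg.mean()) / sd)


def _per_class_sets(pred, gt, classes):
    for c in classes:
        p = pred == c
        g = gt == c
        union = int(np.count_nonzero(p | g))
        inter = int(np.count_nonzero(p & g))
        yield c, inter, union, int(np.count_nonzero(p)), int(np.count_nonzero(g))


def miou(pred: np.ndarray, gt: np.ndarray, classes=DEFAULT_CLASSES) -> float:
    """Mean intersection-over-union; absent-from-both classes score 1."""
    if pred.shape != gt.shape:
        raise ValueError("grid mismatch")
    vals = [1.0 if union == 0 else inter / union
            for _, inter, union, _, _ in _per_class_sets(pred, gt, classes)]
    return float(np.mean(vals))


def mdsc(pred: np.ndarray, gt: np.ndarray, classes=DEFAULT_CLASSES) -> float:
    """Mean Dice coefficient; absent-from-both classes score 1."""
    if pred.shape != gt.shape:
        raise ValueError("grid mismatch")
    vals = [1.0 if (n_p + n_g) == 0 else 2.0 * inter / (n_p + n_g)
            for _, inter, _, n_p, n_g in _per_class_sets(pred, gt, classes)]
    return float(sum(vals) / len(vals))


def r2_score(pred_maps: np.ndarray, gt_maps: np.ndarray) -> float:
    """1 - SS_res / SS_tot pooled over all material channels and pixels."""
    if pred_maps.shape != gt_maps.shape:
        raise ValueError("shape mismatch")
    gt = np.asarray(gt_maps, dtype=float)
    pred = np.asarray(pred_maps, dtype=float)
    ss_tot = float(((gt - gt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("undefined R^2: ground truth is constant")
    return float(1.0 - ((gt - pred) ** 2).sum() / ss_tot)


@dataclass
class MetricsReport:
    rows: dict = field(default_factory=dict)  # method -> metric dict
    fingerprint: dict = field(default_factory=dict)
    notes: dict = field(default_factory=lambda: {"empty_class_convention": "score 1 when absent from both maps"})

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "fingerprint": self.fingerprint, "notes": self.notes},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(rows=d["rows"], fingerprint=d["fingerprint"], notes=d["notes"])

    def to_csv(self) -> str:
        buf = io.StringIO()
        metrics = sorted({k for row in self.rows.values() for k in row})
        w = csv.writer(buf)
        w.writerow(["method"] + metrics)
        for method in sorted(self.rows):
            w.writerow([method] + [self.rows[method].get(m, "") for m in metrics])
        return buf.getvalue()


def evaluate(
    method_labels: dict,
    gt_labels: np.ndarray,
    gt_onehot: np.ndarray | None = None,
    images: dict | None = None,
    roi_set: RoiSet | None = None,
    pitch_mm: float | None = None,
    classes=DEFAULT_CLASSES,
    fingerprint: dict | None = None,
) -> MetricsReport:
    """Assemble mIoU / mDSC / R^2 (and CNR where images + ROIs are given).

    ``method_labels`` maps method name -> categorical map.  R^2 is computed
    on one-hot maps when no continuous ground truth is supplied (recorded in
    the report notes).
    """
    from .network import one_hot

    if gt_onehot is None:
        gt_onehot = one_hot(gt_labels, n_classes=max(classes) + 1)
    report = MetricsReport(fingerprint=fingerprint or {})
    report.notes["r2_basis"] = "one-hot categorical maps"
    for method, lab in method_labels.items():
        if lab.shape != gt_labels.shape:
            raise ValueError(f"{method}: grid mismatch")
        row = {
            "miou": miou(lab, gt_labels, classes),
            "mdsc": mdsc(lab, gt_labels, classes),
            "r2": r2_score(one_hot(lab, n_classes=max(classes) + 1), gt_onehot),
        }
        if images is not None and roi_set is not None and method in images:
            img = images[method]
            bg = roi_mask(img.shape, pitch_mm, roi_set.background)
            cnrs = {}
            for r in roi_set.rois:
                cnrs[r.label or f"roi@{r.center}"] = cnr(img, roi_mask(img.shape, pitch_mm, r), bg)
            row["cnr"] = cnrs
        report.rows[method] = row
    return report
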