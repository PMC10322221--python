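"""Classical vessel-candidate extraction and pixelwise segmentation scoring.

Vessels are dark, elongated structures on the fundus; the classical chain
takes the Otsu dark region of the enhanced grayscale image and keeps the
connected components that look like vessels (elongated, thin, non-trivial
area). Externally produced vessel masks (e.g. from a trained segmentation
network) can be ingested instead and are treated identically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops

__all__ = [
    "VesselFilterConfig",
    "ConfusionCounts",
    "SegScores",
    "otsu_threshold",
    "preselect_vessels",
    "confusion_counts",
    "scores_from_counts",
    "evaluate_segmentation",
    "average_scores",
]

# Label codes for artery/vein masks
AV_BACKGROUND, AV_ARTERY, AV_VEIN, AV_UNKNOWN = 0, 1, 2, 3


@dataclass
class VesselFilterConfig:
    """Morphological preselection rules, at a 1024-px working scale.

    A component is kept when its elongation (major/minor axis ratio of the
    second-moment ellipse) is at least ``min_elongation``, its width
    (2x the maximum interior distance-to-background) is at most
    ``max_width_px``, and its pixel area is at least ``min_area_px``.
    """

    min_elongation: float = 3.0
    max_width_px: float = 40.0
    min_area_px: int = 50


def otsu_threshold(gray: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Otsu threshold over ROI pixels; the dark region is ``gray < t``.

    The returned threshold exactly maximizes the between-class variance
    w0*w1*(mu0 - mu1)^2 over all distinct-intensity cut points (no histogram
    binning, so float-valued enhanced images are handled exactly).

    Raises ``ValueError`` on a constant image (no between-class variance).
    """
    gray = np.asarray(gray, dtype=np.float64)
    values = gray[np.asarray(roi, bool)] if roi is not None else gray.ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    if np.ptp(values) == 0:
        raise ValueError("constant image has no Otsu threshold")
    uniq, counts = np.unique(values, return_counts=True)
    # prefix sums: class 0 = values strictly below each candidate cut uniq[1:]
    csum = np.cumsum(counts)[:-1]
    vsum = np.cumsum(counts * uniq)[:-1]
    n, total = values.size, float((counts * uniq).sum())
    mu0 = vsum / csum
    mu1 = (total - vsum) / (n - csum)
    between = csum * (n - csum) * (mu0 - mu1) ** 2
    return float(uniq[1:][int(np.argmax(between))])


def preselect_vessels(
    dark: np.ndarray,
    roi: np.ndarray | None = None,
    rules: VesselFilterConfig | None = None,
) -> np.ndarray:
    """Filter a dark-region mask down to vessel-like components."""
    rules = rules or VesselFilterConfig()
    dark = np.asarray(dark, bool)
    if roi is not None:
        dark = dark & np.asarray(roi, bool)
    out = np.zeros_like(dark)
    labels = label(dark, connectivity=2)
    for region in regionprops(labels):
        if region.area < rules.min_area_px:
            continue
        minor = region.axis_minor_length
        elong = np.inf if minor < 1e-9 else region.axis_major_length / minor
        if elong < rules.min_elongation:
            continue
        component = labels[region.slice] == region.label
        padded = np.pad(component, 1)  # EDT needs background beyond the crop
        width = 2.0 * ndi.distance_transform_edt(padded).max()
        if width > rules.max_width_px:
            continue
        out[region.slice] |= component
    return out


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class SegScores:
    """Pixelwise overlap scores; undefined ratios (0/0) are NaN."""

    acc: float
    sensitivity: float
    specificity: float
    iou: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "iou": self.iou,
            "dice": self.dice,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, roi: np.ndarray | None = None
) -> ConfusionCounts:
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if roi is not None:
        roi = np.asarray(roi, bool)
        if roi.shape != pred.shape:
            raise ValueError("roi shape differs")
        pred, truth = pred[roi], truth[roi]
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp, tn, fp, fn)


def scores_from_counts(c: ConfusionCounts) -> SegScores:
    """Acc, sensitivity, specificity, IoU and DICE from a confusion matrix.

    Acc  = (TP+TN) / (TP+TN+FP+FN)
    Sens = TP / (TP+FN)          Spec = TN / (TN+FP)
    IoU  = TP / (TP+FP+FN)       DICE = 2 TP / (FP + 2 TP + FN)
    """
    return SegScores(
        acc=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        dice=_ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn),
    )


def evaluate_segmentation(
    pred: np.ndarray, truth: np.ndarray, roi: np.ndarray | None = None
) -> SegScores:
    """Score a predicted mask against ground truth, restricted to the ROI."""
    return scores_from_counts(confusion_counts(pred, truth, roi))


def average_scores(counts: list[ConfusionCounts], mode: str = "pooled") -> SegScores:
    """Aggregate per-image confusion matrices.

    ``pooled`` sums the matrices first (one global confusion matrix);
    ``per_image`` averages each score across images (NaN-aware).
    """
    if not counts:
        raise ValueError("no confusion matrices to aggregate")
    if mode == "pooled":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return scores_from_counts(total)
    if mode == "per_image":
        per = [scores_from_counts(c).as_dict() for c in counts]
        means = {k: float(np.nanmean([p[k] for p in per])) for k in per[0]}
        return SegScores(**means)
    raise ValueError("mode must be 'pooled' or 'per_image'")
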