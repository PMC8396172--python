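"""Detection post-processing and performance metrics.

Detector probability maps are reduced to discrete detections by masking to
the lungs, thresholding, 26-connected labeling, and a minimum-volume filter
(components under 0.15 mm^3 cannot be reliably imaged and are rejected).
A labeled tumor counts as detected on a *direct hit* (voxel overlap with any
detection) or a *near hit* (a detection centroid within 1.5x the tumor's
equivalent-sphere radius of its centroid).  Detections matching no label are
false positives; multiple detections on one label add no extra credit.
Precision = TP/(TP+FP), recall = TP/(TP+FN), and the detection Dice score
2TP/(2TP+FP+FN) summarize the counts; sweeping the decision threshold gives
precision-recall curves whose crossing defines the operating threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .core import BinaryMask, CTVolume, get_logger

__all__ = [
    "ConfusionCounts",
    "DetectionComponent",
    "LabeledTumor",
    "CurvePoint",
    "postprocess",
    "label_components",
    "labeled_tumors",
    "match_detections",
    "precision",
    "recall",
    "detection_dice",
    "threshold_sweep",
    "roc_like_curve",
    "size_binned_rates",
    "NEAR_HIT_FACTOR",
    "MIN_VOLUME_MM3",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_log = get_logger("evaluate")

NEAR_HIT_FACTOR = 1.5
MIN_VOLUME_MM3 = 0.15


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class DetectionComponent:
    """A 26-connected detection region above the decision threshold."""

    voxels: np.ndarray  # (n, 3) integer voxel indices
    volume_mm3: float
    centroid_mm: np.ndarray
    peak_score: float


@dataclass
class LabeledTumor:
    """A ground-truth tumor with its equivalent-sphere radius."""

    voxels: np.ndarray
    volume_mm3: float
    centroid_mm: np.ndarray

    @property
    def equivalent_radius_mm(self) -> float:
        return (3.0 * self.volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class CurvePoint:
    threshold: float
    precision: float
    recall: float
    counts: ConfusionCounts = field(default=None)  # type: ignore[assignment]


# ------------------------------------------------------------- post-processing

def postprocess(
    prob_map: CTVolume,
    lung_mask: BinaryMask,
    threshold: float,
    min_volume_mm3: float = MIN_VOLUME_MM3,
) -> list[DetectionComponent]:
    """Reduce a probability map to filtered detection components.

    Probabilities outside the lung mask are zeroed, the map is binarized at
    ``threshold``, and 26-connected components smaller than
    ``min_volume_mm3`` are rejected.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if prob_map.shape != lung_mask.shape:
        raise ValueError("probability map and lung mask must share a grid")
    p = np.where(lung_mask.as_bool(), prob_map.voxels, 0.0)
    binary = p > threshold
    return label_components(binary, prob_map, min_volume_mm3)


def label_components(
    binary: np.ndarray, prob_map: CTVolume, min_volume_mm3: float = 0.0
) -> list[DetectionComponent]:
    """26-connected components of a binary detection map, volume-filtered."""
    lab, n = ndi.label(binary, structure=_STRUCT26)
    voxvol = prob_map.voxel_volume_mm3
    s_mm = prob_map.spacing_mm
    out = []
    for lid in range(1, n + 1):
        vox = np.argwhere(lab == lid)
        vol = len(vox) * voxvol
        if vol < min_volume_mm3:
            continue
        centroid = vox.mean(axis=0) * s_mm + prob_map.origin_mm
        peak = float(prob_map.voxels[tuple(vox.T)].max())
        out.append(DetectionComponent(vox, vol, centroid, peak))
    return out


def labeled_tumors(labels: BinaryMask) -> list[LabeledTumor]:
    """Split a ground-truth label map into per-tumor components."""
    lab, n = ndi.label(labels.as_bool(), structure=_STRUCT26)
    voxvol = labels.voxel_volume_mm3
    s_mm = labels.spacing_mm
    out = []
    for lid in range(1, n + 1):
        vox = np.argwhere(lab == lid)
        out.append(
            LabeledTumor(
                vox,
                len(vox) * voxvol,
                vox.mean(axis=0) * s_mm + np.asarray(labels.origin_mm),
            )
        )
    return out


# ------------------------------------------------------------------- matching

def match_detections(
    dets: list[DetectionComponent],
    labels: list[LabeledTumor] | BinaryMask,
    *,
    spacing_mm: float | None = None,
    near_hit_factor: float = NEAR_HIT_FACTOR,
) -> ConfusionCounts:
    """Count TP/FP/FN under the direct-hit / near-hit criterion.

    A label is detected (one TP, however many detections land on it) when any
    detection overlaps it, or any detection centroid lies within
    ``near_hit_factor`` times its equivalent radius of its centroid.
    Detections matching no label are FPs; a detection overlapping two labels
    credits both and is no FP.
    """
    if isinstance(labels, BinaryMask):
        spacing_mm = labels.spacing_mm
        labels = labeled_tumors(labels)
    label_hit = [False] * len(labels)
    det_matched = [False] * len(dets)

    label_sets = [set(map(tuple, t.voxels)) for t in labels]
    for d_i, det in enumerate(dets):
        det_vox = set(map(tuple, det.voxels))
        for l_i, (tumor, lset) in enumerate(zip(labels, label_sets)):
            direct = not det_vox.isdisjoint(lset)
            near = (
                np.linalg.norm(det.centroid_mm - tumor.centroid_mm)
                <= near_hit_factor * tumor.equivalent_radius_mm
            )
            if direct or near:
                label_hit[l_i] = True
                det_matched[d_i] = True
    tp = sum(label_hit)
    fn = len(labels) - tp
    fp = sum(1 for m in det_matched if not m)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


# -------------------------------------------------------------------- metrics

def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        _log.warning("precision undefined (TP + FP = 0); reporting 0")
        return 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        _log.warning("recall undefined (TP + FN = 0); reporting 0")
        return 0.0
    return c.tp / (c.tp + c.fn)


def detection_dice(c: ConfusionCounts) -> float:
    """Detection Dice 2TP/(2TP+FP+FN), the harmonic mean of P and R."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("detection Dice undefined for all-zero counts")
    return 2 * c.tp / denom


# --------------------------------------------------------------------- curves

def _counts_over_thresholds(prob_maps, labels, lung_masks, thresholds):
    per_threshold = []
    tumor_lists = [labeled_tumors(lbl) for lbl in labels]
    for t in thresholds:
        total = ConfusionCounts(0, 0, 0)
        for pm, tl, lm in zip(prob_maps, tumor_lists, lung_masks):
            dets = postprocess(pm, lm, t)
            total = total + match_detections(dets, tl)
        per_threshold.append(total)
    return per_threshold


def threshold_sweep(
    prob_maps: list[CTVolume],
    labels: list[BinaryMask],
    lung_masks: list[BinaryMask],
    thresholds: np.ndarray | None = None,
) -> tuple[list[CurvePoint], float]:
    """Precision/recall over a threshold grid and the P=R crossing.

    The operating threshold is where |P - R| is minimal, refined by linear
    interpolation between the adjacent grid points that bracket the sign
    change of P - R.  If predictions are empty at every threshold, a warning
    is issued and the argmax-Dice threshold is returned instead.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds")
    counts = _counts_over_thresholds(prob_maps, labels, lung_masks, thresholds)
    points = [
        CurvePoint(float(t), precision(c), recall(c), c) for t, c in zip(thresholds, counts)
    ]
    if all(c.tp + c.fp == 0 for c in counts):
        warnings.warn("no detections at any threshold; returning argmax-Dice threshold")
        dices = [2 * c.tp / max(2 * c.tp + c.fp + c.fn, 1) for c in counts]
        return points, float(thresholds[int(np.argmax(dices))])

    diff = np.array([p.precision - p.recall for p in points])
    # interpolate the crossing if the sign changes between grid points
    sign_change = np.where(np.diff(np.signbit(diff)))[0]
    if len(sign_change) > 0:
        i = int(sign_change[0])
        d0, d1 = diff[i], diff[i + 1]
        if d1 == d0:
            t_opt = thresholds[i]
        else:
            frac = -d0 / (d1 - d0)
            t_opt = thresholds[i] + frac * (thresholds[i + 1] - thresholds[i])
    else:
        t_opt = thresholds[int(np.argmin(np.abs(diff)))]
        if np.allclose(diff, 0.0):
            _log.info("degenerate plateau: precision equals recall across the sweep")
    return points, float(t_opt)


def roc_like_curve(
    prob_maps: list[CTVolume],
    labels: list[BinaryMask],
    lung_masks: list[BinaryMask],
    thresholds: np.ndarray | None = None,
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC-like curve (TPR vs pseudo-FPR) and its trapezoidal AUC.

    Detection tasks have no true negatives, so the abscissa is a *pseudo*
    false-positive rate FP(t)/max_t FP(t).  AUC values are therefore not
    comparable to conventional voxel- or case-level ROC AUCs.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    counts = _counts_over_thresholds(prob_maps, labels, lung_masks, thresholds)
    tpr = np.array([recall(c) for c in counts])
    fp = np.array([c.fp for c in counts], dtype=float)
    max_fp = fp.max()
    fpr = fp / max_fp if max_fp > 0 else np.zeros_like(fp)
    curve = [(float(t), float(f), float(r)) for t, f, r in zip(thresholds, fpr, tpr)]
    # monotone staircase upper hull: best TPR attainable at or below each FPR
    order = np.argsort(fpr, kind="stable")
    xs, ys = fpr[order], tpr[order]
    ys = np.maximum.accumulate(ys)
    xs = np.concatenate([[0.0], xs, [1.0]])
    ys = np.concatenate([[ys[0] if len(ys) else 0.0], ys, [ys[-1] if len(ys) else 0.0]])
    auc = float(np.trapezoid(ys, xs))
    return curve, auc


def size_binned_rates(
    labels: list[LabeledTumor] | BinaryMask,
    dets: list[DetectionComponent],
    bin_edges_mm3: tuple[float, ...] = (0.15, 0.25, 0.5, 1.0, 5.0, np.inf),
    *,
    near_hit_factor: float = NEAR_HIT_FACTOR,
) -> list[float]:
    """Per-size-bin fraction of labeled tumors detected (NaN for empty bins)."""
    if isinstance(labels, BinaryMask):
        labels = labeled_tumors(labels)
    edges = np.asarray(bin_edges_mm3, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    hits = np.zeros(len(labels), dtype=bool)
    for l_i, tumor in enumerate(labels):
        lset = set(map(tuple, tumor.voxels))
        for det in dets:
            direct = not lset.isdisjoint(set(map(tuple, det.voxels)))
            near = (
                np.linalg.norm(det.centroid_mm - tumor.centroid_mm)
                <= near_hit_factor * tumor.equivalent_radius_mm
            )
            if direct or near:
                hits[l_i] = True
                break
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [i for i, t in enumerate(labels) if lo <= t.volume_mm3 < hi]
        rates.append(float(np.mean(hits[in_bin])) if in_bin else float("nan"))
    return rates
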