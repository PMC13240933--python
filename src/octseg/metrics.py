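"""Segmentation evaluation suite.

Implements the full pixel-overlap and boundary-distance panel used to
compare a predicted epidermis mask against its ground truth: accuracy,
precision, recall, Jaccard index (IoU), Dice coefficient, mean absolute
error (MAE), and the (max-form) Hausdorff distance between mask
boundaries, together with the qualitative performance bands commonly used
to read them (overlap scores > 0.7 acceptable, > 0.8 good, > 0.93
excellent; MAE < 1 px good, 1-1.5 px acceptable; Hausdorff < 25 px good,
25-70 px acceptable).

Conventions
-----------
* Coordinates are (row, col), 0-based, row increasing with depth;
  distances in pixel units.
* Boundary pixels are foreground pixels 4-adjacent to background or to
  the image border (so a band touching the edge still has a closed
  boundary).
* Division by zero: precision with no predicted foreground is reported as
  NaN with a warning (scored 0 in aggregates); Dice/Jaccard between two
  empty masks is 1 — agreement on emptiness is genuine agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ConfusionCounts", "MetricReport", "binarize", "confusion",
           "overlap_metrics", "mean_absolute_error", "extract_boundary",
           "hausdorff", "evaluate", "EmptyMaskError"]


class EmptyMaskError(ValueError):
    """A boundary-distance operand has no foreground pixels."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion tallies for one predicted/truth mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    jaccard: float
    dice: float
    mae: float
    hausdorff: float
    bands: dict

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "jaccard": self.jaccard,
                "dice": self.dice, "mae": self.mae,
                "hausdorff": self.hausdorff}


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; foreground iff value >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN pixel tallies; counts always sum to the pixel total."""
    pred, truth = _as_bool(pred), _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def overlap_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, Jaccard and Dice from one table."""
    n = c.n
    if n == 0:
        raise ValueError("empty confusion table (N = 0)")
    accuracy = (c.tp + c.tn) / n
    if c.tp + c.fp == 0:
        warnings.warn("no predicted foreground: precision undefined",
                      RuntimeWarning, stacklevel=2)
        precision = float("nan")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("no true foreground: recall undefined",
                      RuntimeWarning, stacklevel=2)
        recall = float("nan")
    else:
        recall = c.tp / (c.tp + c.fn)
    if c.tp + c.fp + c.fn == 0:
        jaccard = 1.0   # both masks empty: perfect agreement on emptiness
        dice = 1.0
    else:
        jaccard = c.tp / (c.tp + c.fp + c.fn)
        dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "jaccard": jaccard, "dice": dice}


def mean_absolute_error(pred: np.ndarray, truth: np.ndarray,
                        soft: bool = False) -> float:
    """Mean absolute per-pixel difference.

    With binary masks this equals (FP + FN) / N. ``soft=True`` accepts a
    probability map for ``pred`` and averages |p - y| directly.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if soft:
        return float(np.mean(np.abs(pred.astype(np.float64)
                                    - _as_bool(truth).astype(np.float64))))
    return float(np.mean(_as_bool(pred) ^ _as_bool(truth)))


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask as an (M, 2) array of (row, col).

    A foreground pixel is on the boundary when at least one of its four
    edge-neighbours is background, or when it lies on the image border.
    Empty masks yield an empty (0, 2) array.
    """
    m = _as_bool(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    return np.argwhere(boundary)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two boundary point sets.

    max( max_{p in A} min_{q in B} d(p,q), max_{q in B} min_{p in A} d(p,q) )
    with exact Euclidean distances; zero iff the sets are equal.
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if len(a) == 0:
        raise EmptyMaskError("empty prediction boundary: segmentation "
                             "produced no foreground")
    if len(b) == 0:
        raise EmptyMaskError("empty truth boundary: ground-truth mask has "
                             "no foreground")
    d_ab = cKDTree(b).query(a, k=1)[0].max()
    d_ba = cKDTree(a).query(b, k=1)[0].max()
    return float(max(d_ab, d_ba))


_OVERLAP_BANDS = ((0.93, "excellent"), (0.8, "good"), (0.7, "acceptable"))


def _band_overlap(v: float) -> str:
    if np.isnan(v):
        return "undefined"
    for cut, label in _OVERLAP_BANDS:
        if v > cut:
            return label
    return "poor"


def _band_mae(v: float) -> str:
    if v < 1.0:
        return "good"
    if v <= 1.5:
        return "acceptable"
    return "poor"


def _band_hausdorff(v: float) -> str:
    if v < 25.0:
        return "good"
    if v <= 70.0:
        return "acceptable"
    return "poor"


def evaluate(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Full seven-metric report plus qualitative bands for one mask pair."""
    c = confusion(pred, truth)
    om = overlap_metrics(c)
    mae = mean_absolute_error(pred, truth)
    hd = hausdorff(extract_boundary(pred), extract_boundary(truth))
    bands = {k: _band_overlap(v) for k, v in om.items()}
    bands["mae"] = _band_mae(mae)
    bands["hausdorff"] = _band_hausdorff(hd)
    return MetricReport(**om, mae=mae, hausdorff=hd, bands=bands)
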