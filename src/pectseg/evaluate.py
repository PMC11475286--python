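"""Per-class validation: Dice, Jaccard, confusion matrix, CDF/threshold
summaries, and area-error accounting.

For a predicted label raster P and ground truth G, and a class k with
pixel sets Pk and Gk:

    Dice    D_k = 2 |Pk ∩ Gk| / (|Pk| + |Gk|)
    Jaccard J_k = |Pk ∩ Gk| / |Pk ∪ Gk|        (IoU; J = D / (2 - D))

When a class is absent from both masks the score is defined as 1 (a
vacuously perfect match); absent from exactly one, 0. The confusion
matrix is normalized by the grand pixel total, so its diagonal sum is
the overall pixel accuracy. Area-error rows compare summed predicted and
ground-truth areas per class, with the relative error taken against the
ground-truth (radiologist) area and reported to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLASS_NAMES, N_CLASSES, as_pixels

__all__ = [
    "ClassMetric",
    "AreaErrorRow",
    "dice_per_class",
    "jaccard_per_class",
    "per_class_metrics",
    "confusion_matrix",
    "cdf_summary",
    "threshold_analysis",
    "area_error_row",
    "area_error_table",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class ClassMetric:
    """Aggregate and per-image overlap scores for one class."""

    class_id: int
    dice: float
    jaccard: float
    per_image_dice: list[float]
    per_image_jaccard: list[float]


@dataclass(frozen=True)
class AreaErrorRow:
    """One class's row of the area accounting table."""

    class_id: int
    class_name: str
    predicted_area_px: int
    truth_area_px: int
    mean_jaccard: float
    mean_dice: float
    absolute_error: int
    relative_error: float


def _overlap_counts(pred, truth, k: int) -> tuple[int, int, int]:
    p = as_pixels(pred)
    g = as_pixels(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    pk = p == k
    gk = g == k
    inter = int(np.count_nonzero(pk & gk))
    return inter, int(pk.sum()), int(gk.sum())


def dice_per_class(pred, truth, k: int) -> float:
    """Dice coefficient 2|Pk∩Gk| / (|Pk| + |Gk|) for class ``k``."""
    inter, np_, ng = _overlap_counts(pred, truth, k)
    if np_ + ng == 0:
        return 1.0
    return 2.0 * inter / (np_ + ng)


def jaccard_per_class(pred, truth, k: int) -> float:
    """Jaccard index |Pk∩Gk| / |Pk∪Gk| (IoU) for class ``k``."""
    inter, np_, ng = _overlap_counts(pred, truth, k)
    union = np_ + ng - inter
    if union == 0:
        return 1.0
    return inter / union


def per_class_metrics(preds, truths, n_classes: int = N_CLASSES) -> list[ClassMetric]:
    """Per-image Dice/Jaccard lists and their means, one entry per class."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError(f"misaligned collections: {len(preds)} preds vs {len(truths)} truths")
    if not preds:
        raise ValueError("empty collections")
    out = []
    for k in range(n_classes):
        d = [dice_per_class(p, t, k) for p, t in zip(preds, truths)]
        j = [jaccard_per_class(p, t, k) for p, t in zip(preds, truths)]
        out.append(ClassMetric(class_id=k, dice=float(np.mean(d)), jaccard=float(np.mean(j)),
                               per_image_dice=d, per_image_jaccard=j))
    return out


def confusion_matrix(pred, truth, n_classes: int = N_CLASSES,
                     normalize: str = "total") -> np.ndarray:
    """C[i, j] = pixels of true class i predicted as class j.

    ``normalize="total"`` divides by the grand pixel count so all entries
    sum to 1 and the diagonal sums to the overall pixel accuracy;
    ``normalize="none"`` returns raw counts.
    """
    p = as_pixels(pred).ravel()
    g = as_pixels(truth).ravel()
    if p.shape != g.shape:
        raise ValueError("shape mismatch between pred and truth")
    if p.max(initial=0) >= n_classes or g.max(initial=0) >= n_classes:
        raise ValueError(f"label out of range for n_classes={n_classes}")
    counts = np.bincount(g.astype(np.int64) * n_classes + p.astype(np.int64),
                         minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    if normalize == "none":
        return counts
    if normalize == "total":
        return counts / counts.sum()
    raise ValueError(f"unknown normalization {normalize!r}")


def cdf_summary(values) -> pd.DataFrame:
    """Empirical CDF of a list of scores in [0, 1].

    Returns a right-continuous step table with one row per distinct
    value: columns ``threshold`` and ``cumulative`` = P(score <= threshold),
    reaching 1 at the maximum value.
    """
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty value list")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("values must lie in [0, 1]")
    uniq, counts = np.unique(vals, return_counts=True)
    return pd.DataFrame({"threshold": uniq,
                         "cumulative": np.cumsum(counts) / vals.size})


def threshold_analysis(values, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Percent of images whose score meets or exceeds each threshold."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty value list")
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    pct = [100.0 * np.count_nonzero(vals >= t) / vals.size for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "percent_at_or_above": pct})


def area_error_row(
    class_id: int, predicted_area: int, truth_area: int,
    mean_dice: float = np.nan, mean_jaccard: float = np.nan,
) -> AreaErrorRow:
    """Area accounting for one class from summed pixel areas."""
    if truth_area < 0 or predicted_area < 0:
        raise ValueError("areas must be non-negative")
    absolute = abs(int(predicted_area) - int(truth_area))
    if truth_area == 0:
        relative = 0.0 if absolute == 0 else float("nan")
    else:
        relative = round(absolute / truth_area, 3)
    return AreaErrorRow(
        class_id=class_id,
        class_name=CLASS_NAMES.get(class_id, str(class_id)),
        predicted_area_px=int(predicted_area),
        truth_area_px=int(truth_area),
        mean_jaccard=mean_jaccard,
        mean_dice=mean_dice,
        absolute_error=absolute,
        relative_error=relative,
    )


def area_error_table(preds, truths, n_classes: int = N_CLASSES) -> list[AreaErrorRow]:
    """Per-class area accounting over aligned prediction/truth collections."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError(f"misaligned collections: {len(preds)} preds vs {len(truths)} truths")
    if not preds:
        raise ValueError("empty collections")
    metrics = per_class_metrics(preds, truths, n_classes=n_classes)
    rows = []
    for k in range(n_classes):
        pred_area = sum(int(np.count_nonzero(as_pixels(p) == k)) for p in preds)
        truth_area = sum(int(np.count_nonzero(as_pixels(t) == k)) for t in truths)
        rows.append(area_error_row(k, pred_area, truth_area,
                                   mean_dice=round(metrics[k].dice, 2),
                                   mean_jaccard=round(metrics[k].jaccard, 2)))
    return rows


def area_table_frame(rows: list[AreaErrorRow]) -> pd.DataFrame:
    """Tabular view of area-error rows, column order matching the report."""
    return pd.DataFrame([{
        "class": r.class_name,
        "predicted_area_px": r.predicted_area_px,
        "truth_area_px": r.truth_area_px,
        "mean_jaccard": r.mean_jaccard,
        "mean_dice": r.mean_dice,
        "absolute_error": r.absolute_error,
        "relative_error": r.relative_error,
    } for r in rows])
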