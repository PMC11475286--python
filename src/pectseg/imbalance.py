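"""Class-imbalance machinery: frequency-derived loss weights and losses.

In an MLO mammogram the background outweighs the breast, which in turn
outweighs the pectoral muscle, so an unweighted pixel loss is dominated
by the easy, prevalent classes. The remedy used here weights the binary
pixel cross-entropy by the complementary pixel frequencies of the
segmented region:

    alpha = lambda * Y+ / (Y+ + Y-)        (weight of the y = 0 term)
    beta  =          Y- / (Y+ + Y-)        (weight of the y = 1 term)

where ``Y+``/``Y-`` count pixels inside/outside the segmented region in
the training masks and ``lambda`` is a tuning factor on the prevalent
(outside) side. Each side is thus weighted by the *other* side's
frequency: the rare positive class receives the large weight.

The three-class generalization assigns each class its one-vs-rest
complement frequency, ``w_k = 1 - f_k``, with the background class — the
"outside the segmented regions" side — additionally scaled by lambda,
and the vector normalized to sum to the number of classes. For two
classes and the un-normalized vector this reduces exactly to
(alpha, beta); for perfectly balanced data at lambda = 1 it reduces to
unweighted cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BACKGROUND, N_CLASSES, as_pixels

__all__ = [
    "ClassCounts",
    "ClassWeights",
    "LossValue",
    "count_class_pixels",
    "compute_weights",
    "one_vs_rest_class_weights",
    "weighted_pixel_loss",
    "multiclass_weighted_ce",
    "combined_objective",
]

#: Probabilities and sigmoids are clamped to this range so saturated
#: predictions yield a large finite loss instead of an infinity.
_EPS = 1e-7


@dataclass(frozen=True)
class ClassCounts:
    """Pixel counts inside (Y+) and outside (Y-) the segmented region."""

    y_plus: int
    y_minus: int
    per_class: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.y_plus < 0 or self.y_minus < 0:
            raise ValueError("pixel counts must be non-negative")

    @property
    def total(self) -> int:
        return self.y_plus + self.y_minus


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights: binary (alpha, beta) and/or a per-class vector."""

    alpha: float
    beta: float
    lam: float = 1.0
    per_class: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class LossValue:
    """A combined objective: classification term + segmentation term."""

    l_class: float
    l_seg: float

    @property
    def total(self) -> float:
        return self.l_class + self.l_seg


def count_class_pixels(masks, positive_class: int, n_classes: int = N_CLASSES) -> ClassCounts:
    """Count pixels inside/outside class ``positive_class`` over a mask set."""
    masks = list(masks)
    if not masks:
        raise ValueError("mask collection is empty")
    per_class = np.zeros(n_classes, dtype=np.int64)
    for m in masks:
        per_class += np.bincount(as_pixels(m).ravel(), minlength=n_classes)[:n_classes]
    y_plus = int(per_class[positive_class])
    return ClassCounts(y_plus=y_plus, y_minus=int(per_class.sum() - y_plus),
                       per_class=tuple(int(c) for c in per_class))


def compute_weights(counts: ClassCounts, lam: float = 1.0) -> ClassWeights:
    """Binary weights: alpha = lam * Y+/(Y+ + Y-), beta = Y-/(Y+ + Y-)."""
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    if counts.total == 0:
        raise ValueError("zero total pixels: weights undefined")
    alpha = lam * counts.y_plus / counts.total
    beta = counts.y_minus / counts.total
    return ClassWeights(alpha=alpha, beta=beta, lam=lam)


def one_vs_rest_class_weights(
    masks, lam: float = 1.0, n_classes: int = N_CLASSES,
    background_class: int = BACKGROUND, normalize: bool = True,
) -> ClassWeights:
    """Per-class weights ``w_k = 1 - f_k`` (background scaled by lambda).

    ``f_k`` is the pixel frequency of class ``k`` over the training
    masks. Each class is treated one-vs-rest as the segmented region, so
    its pixels receive the complement-frequency weight ``Y-_k / total``;
    the background class — outside every segmented region — carries the
    tuning factor lambda. When ``normalize`` is set the vector is scaled
    to sum to ``n_classes`` so the loss magnitude stays comparable to the
    unweighted case.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    counts = count_class_pixels(masks, positive_class=0, n_classes=n_classes)
    per_class = np.asarray(counts.per_class, dtype=np.float64)
    total = per_class.sum()
    if total == 0:
        raise ValueError("zero total pixels: weights undefined")
    freq = per_class / total
    w = 1.0 - freq
    w[background_class] *= lam
    if normalize:
        if w.sum() == 0:
            raise ValueError("degenerate weights: all classes have frequency 1")
        w = w * (n_classes / w.sum())
    # Binary view for reference: alpha is the background-side weight,
    # beta the largest foreground-side weight.
    return ClassWeights(alpha=float(w[background_class]),
                        beta=float(np.delete(w, background_class).max()),
                        lam=lam, per_class=tuple(float(v) for v in w))


def weighted_pixel_loss(score: float, label: int, w: ClassWeights) -> float:
    """Weighted binary cross-entropy for one pixel given a raw score.

    ``-alpha * log(1 - sigmoid(score))`` for label 0 and
    ``-beta * log(sigmoid(score))`` for label 1; non-negative and
    approaching 0 as the correct-class probability approaches 1.
    """
    if label not in (0, 1):
        raise ValueError(f"binary label expected, got {label}")
    sig = 1.0 / (1.0 + np.exp(-float(score)))
    sig = min(max(sig, _EPS), 1.0 - _EPS)
    if label == 1:
        return -w.beta * float(np.log(sig))
    return -w.alpha * float(np.log(1.0 - sig))


def multiclass_weighted_ce(prob_map: np.ndarray, truth, weights: ClassWeights) -> float:
    """Mean weighted cross-entropy over pixels: ``w_k(p) * (-log p_k(p))``.

    ``prob_map`` has shape ``(H, W, K)`` with per-pixel class
    probabilities summing to 1 (checked to 1e-6); ``truth`` is an
    ``(H, W)`` label raster; ``weights.per_class`` supplies ``w_k``.
    """
    probs = np.asarray(prob_map, dtype=np.float64)
    y = as_pixels(truth)
    if probs.ndim != 3 or probs.shape[:2] != y.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {y.shape}")
    if not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probability rows are not normalized to 1 (tol 1e-6)")
    k = probs.shape[-1]
    if not weights.per_class or len(weights.per_class) != k:
        raise ValueError(f"weights.per_class must have {k} entries")
    w = np.asarray(weights.per_class, dtype=np.float64)
    p_true = np.clip(np.take_along_axis(probs, y[..., None].astype(int), axis=-1)[..., 0],
                     _EPS, 1.0)
    return float(np.mean(w[y] * (-np.log(p_true))))


def combined_objective(l_class: float, l_seg: float) -> LossValue:
    """Total objective = classification term + segmentation term."""
    if not (np.isfinite(l_class) and np.isfinite(l_seg)):
        raise ValueError(f"non-finite loss components: ({l_class}, {l_seg})")
    return LossValue(l_class=float(l_class), l_seg=float(l_seg))
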