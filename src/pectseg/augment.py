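"""Mask-consistent random affine augmentation (translation, rotation, scale).

Each augmented copy applies one affine transform to the image and the
*same* transform to its label mask. Images are resampled bilinearly,
masks with nearest-neighbour so the label set stays within {0, 1, 2};
regions swept in from outside the frame are filled with background class
0 and intensity 0. Defaults follow the common MLO augmentation recipe:
translations of up to 10 pixels in any direction, rotations within a
30-degree range, and a mild scale interval.

By default each copy draws a single transform type — cycling through
translation, rotation, scale — so three copies per source quadruple the
dataset (322 sources -> 1288 items); composed transforms are available
via ``AugmentationSpec(compose=True)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageGrid, LabelMask, as_pixels

__all__ = [
    "AugmentationSpec",
    "AffineParams",
    "AugmentedItem",
    "sample_affine_params",
    "apply_affine",
    "random_affine",
    "augment_dataset",
    "write_provenance_csv",
]

PROVENANCE_HEADER = ["item_id", "source_id", "dx", "dy", "theta_deg", "scale"]

_TRANSFORM_CYCLE = ("translation", "rotation", "scale")


@dataclass(frozen=True)
class AugmentationSpec:
    """Sampling ranges for the affine transforms."""

    max_translation: float = 10.0  # pixels, each axis
    max_rotation: float = 30.0  # degrees, sampled in [-max, +max]
    scale_range: tuple[float, float] = (0.9, 1.1)
    compose: bool = False  # True: draw all three per copy
    seed: int = 0

    def validate(self) -> None:
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")
        if not 0 <= self.max_rotation <= 180:
            raise ValueError("max_rotation must lie in [0, 180]")
        lo, hi = self.scale_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"scale_range must be positive and ordered, got {self.scale_range}")


@dataclass(frozen=True)
class AffineParams:
    """One realized transform: shift (pixels), rotation (deg), scale factor."""

    dx: float = 0.0
    dy: float = 0.0
    theta_deg: float = 0.0
    scale: float = 1.0

    @property
    def is_identity(self) -> bool:
        return self.dx == 0 and self.dy == 0 and self.theta_deg == 0 and self.scale == 1


@dataclass
class AugmentedItem:
    image: ImageGrid
    mask: LabelMask
    item_id: str
    source_id: str
    params: AffineParams


def sample_affine_params(
    spec: AugmentationSpec, rng: np.random.Generator, kind: str = "compose"
) -> AffineParams:
    """Draw transform parameters; ``kind`` picks one type or ``"compose"``."""
    dx = dy = 0.0
    theta = 0.0
    scale = 1.0
    if kind in ("translation", "compose"):
        dx = float(rng.uniform(-spec.max_translation, spec.max_translation))
        dy = float(rng.uniform(-spec.max_translation, spec.max_translation))
    if kind in ("rotation", "compose"):
        theta = float(rng.uniform(-spec.max_rotation, spec.max_rotation))
    if kind in ("scale", "compose"):
        scale = float(rng.uniform(*spec.scale_range))
    if kind not in (*_TRANSFORM_CYCLE, "compose"):
        raise ValueError(f"unknown transform kind {kind!r}")
    return AffineParams(dx=dx, dy=dy, theta_deg=theta, scale=scale)


def apply_affine(
    image: ImageGrid | np.ndarray, mask: LabelMask | np.ndarray, params: AffineParams
) -> tuple[ImageGrid, LabelMask]:
    """Apply one affine transform to an aligned image/mask pair.

    The transform rotates by ``theta_deg`` and scales by ``scale`` about
    the image center, then shifts by ``(dx, dy)`` (columns, rows). The
    identity parameter set returns bit-equal copies.
    """
    img = as_pixels(image)
    msk = as_pixels(mask)
    if img.shape != msk.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {msk.shape}")

    src_id = getattr(image, "source_id", "")
    if params.is_identity:
        out_img, out_msk = img.copy(), msk.copy()
    else:
        h, w = img.shape
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        th = np.deg2rad(params.theta_deg)
        # Forward map: output = s * R(theta) @ (input - c) + c + t.
        # affine_transform needs the inverse: input = M @ output + offset.
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        inv = rot.T / params.scale  # (s R)^-1, row/col convention
        shift = np.array([params.dy, params.dx])
        offset = center - inv @ (center + shift)
        out_img = ndimage.affine_transform(img.astype(np.float64), inv, offset=offset,
                                           order=1, mode="constant", cval=0.0)
        out_img = np.clip(out_img, 0.0, None).astype(img.dtype if
                                                     np.issubdtype(img.dtype, np.floating)
                                                     else np.float32)
        out_msk = ndimage.affine_transform(msk, inv, offset=offset, order=0,
                                           mode="constant", cval=0)
    return (
        ImageGrid(out_img, bit_depth=getattr(image, "bit_depth", 8),
                  spacing=getattr(image, "spacing", None), source_id=src_id),
        LabelMask(out_msk, source_id=getattr(mask, "source_id", "")),
    )


def random_affine(
    image: ImageGrid | np.ndarray,
    mask: LabelMask | np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
    kind: str = "compose",
) -> tuple[ImageGrid, LabelMask, AffineParams]:
    """Sample one transform from ``spec`` and apply it to both rasters."""
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    params = sample_affine_params(spec, rng, kind=kind)
    out_img, out_msk = apply_affine(image, mask, params)
    return out_img, out_msk, params


def augment_dataset(
    pairs, copies_per_source: int, spec: AugmentationSpec, seed: int | None = None
) -> list[AugmentedItem]:
    """Expand a dataset to ``n_source * (1 + copies_per_source)`` items.

    Originals come first (identity provenance); each copy applies one
    transform type from the translation/rotation/scale cycle, or a
    composition of all three when ``spec.compose`` is set. Transform
    parameters are logged per item for exact replay.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot augment an empty dataset")
    if copies_per_source < 0:
        raise ValueError("copies_per_source must be >= 0")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    items: list[AugmentedItem] = []
    for i, (image, mask) in enumerate(pairs):
        src = getattr(image, "source_id", "") or f"source-{i:04d}"
        items.append(AugmentedItem(
            image=image if isinstance(image, ImageGrid) else ImageGrid(image),
            mask=mask if isinstance(mask, LabelMask) else LabelMask(mask),
            item_id=f"{src}/orig", source_id=src, params=AffineParams(),
        ))
    for i, (image, mask) in enumerate(pairs):
        src = getattr(image, "source_id", "") or f"source-{i:04d}"
        for c in range(copies_per_source):
            kind = "compose" if spec.compose else _TRANSFORM_CYCLE[c % 3]
            params = sample_affine_params(spec, rng, kind=kind)
            aug_img, aug_msk = apply_affine(image, mask, params)
            items.append(AugmentedItem(
                image=aug_img, mask=aug_msk,
                item_id=f"{src}/aug{c}", source_id=src, params=params,
            ))
    return items


def write_provenance_csv(items: list[AugmentedItem], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROVENANCE_HEADER)
        for it in items:
            p = it.params
            writer.writerow([it.item_id, it.source_id,
                             f"{p.dx:.6f}", f"{p.dy:.6f}", f"{p.theta_deg:.6f}",
                             f"{p.scale:.6f}"])
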