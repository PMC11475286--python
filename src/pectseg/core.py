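"""Shared raster containers used across the pipeline.

All rasters are 2-D, row-major, 0-based, origin at the top-left corner
(row = y, column = x). Images carry intensities within a declared bit
depth; label masks take values in {0 = background, 1 = breast,
2 = pectoral muscle}; binary masks take values in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class codes shared by every stage.
BACKGROUND, BREAST, MUSCLE = 0, 1, 2
N_CLASSES = 3
CLASS_NAMES = {BACKGROUND: "background", BREAST: "breast", MUSCLE: "pectoral_muscle"}


@dataclass
class ImageGrid:
    """A 2-D grayscale intensity raster with acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 8
    spacing: tuple[float, float] | None = None  # (row, col) in mm/pixel
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImageGrid expects a 2-D raster, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("ImageGrid intensities must be non-negative")
        if np.nanmax(self.pixels, initial=0) > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities exceed declared bit depth {self.bit_depth} "
                f"(max={self.pixels.max()})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """A 3-class ground-truth / prediction raster aligned to an ImageGrid."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"LabelMask expects a 2-D raster, got shape {self.pixels.shape}")
        values = np.unique(self.pixels)
        if not np.isin(values, (BACKGROUND, BREAST, MUSCLE)).all():
            raise ValueError(f"LabelMask values must lie in {{0,1,2}}, got {values}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A foreground/background raster over {0, 1}."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"BinaryMask expects a 2-D raster, got shape {self.pixels.shape}")
        values = np.unique(self.pixels)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"BinaryMask values must lie in {{0,1}}, got {values}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(obj) -> np.ndarray:
    """Return the underlying 2-D array of a raster container or ndarray."""
    if isinstance(obj, (ImageGrid, LabelMask, BinaryMask)):
        return obj.pixels
    return np.asarray(obj)
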