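"""Mammogram preprocessing: ingestion, contrast windowing, breast isolation.

The cleaning pipeline reduces a raw MLO mammogram from four effective
classes (breast, muscle, background, burned-in annotations) to three by

1. binarizing the image (Otsu by default),
2. labelling 4-connected foreground islands,
3. keeping the largest island — the breast together with the attached
   pectoral wedge — and
4. zeroing every other island while exporting its statistics to a CSV
   metadata record, so no burned-in information is silently discarded.

Contrast enhancement maps raw detector values through a value-of-interest
look-up table (VOI LUT); when no window is available a full-range linear
(min-max) window is used. By default enhancement runs after masking and
segmentation; ``preprocess_mammogram`` exposes a switch to run it first.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BinaryMask, ImageGrid, as_pixels

__all__ = [
    "VOIWindow",
    "IslandSet",
    "AnnotationRecord",
    "read_mammogram",
    "apply_voi_lut",
    "binarize",
    "connected_components",
    "select_breast_region",
    "strip_annotations",
    "preprocess_mammogram",
    "write_annotation_records",
]

#: 4-connectivity structuring element: edge-sharing neighbours only.
FOUR_CONNECTIVITY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

ANNOTATION_CSV_HEADER = ["island_id", "area_px", "xmin", "ymin", "xmax", "ymax", "mean_intensity"]


@dataclass(frozen=True)
class VOIWindow:
    """A linear DICOM-style intensity window (center, width)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"degenerate VOI window: width={self.width} must be > 0")


@dataclass
class IslandSet:
    """Labelled 4-connected components of a binary mask.

    ``labels`` is 0 on background; islands are numbered 1..n_islands in
    raster-scan order of first occurrence. ``areas[k]`` is the pixel area
    of island ``k + 1``.
    """

    labels: np.ndarray
    areas: np.ndarray
    source_id: str = ""

    @property
    def n_islands(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class AnnotationRecord:
    """Metadata for a non-breast island removed during cleaning."""

    island_id: int
    area_px: int
    xmin: int
    ymin: int
    xmax: int
    ymax: int
    mean_intensity: float
    reason: str = "non-maximal island"


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def read_mammogram(path: str | Path, format: str | None = None) -> ImageGrid:
    """Read a DICOM, PNG or PGM mammogram into an :class:`ImageGrid`.

    ``format`` may be ``"dicom"``, ``"png"`` or ``"pgm"``; when omitted it
    is inferred from the file extension. No rescaling or windowing is
    applied — raw stored intensities are preserved. For DICOM input the
    pixel spacing and any linear VOI window found in the metadata are
    attached to the returned grid (``grid.spacing``, ``grid.voi``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".dcm": "dicom", ".dicom": "dicom", ".png": "png", ".pgm": "pgm"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from extension {ext!r}; pass format=")

    if format == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        if "PixelData" not in ds:
            raise ValueError(f"{path}: DICOM dataset has no PixelData element")
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected single-frame grayscale PixelData")
        spacing = None
        if "PixelSpacing" in ds:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        elif "ImagerPixelSpacing" in ds:
            spacing = (float(ds.ImagerPixelSpacing[0]), float(ds.ImagerPixelSpacing[1]))
        bit_depth = int(getattr(ds, "BitsStored", 16))
        grid = ImageGrid(arr, bit_depth=bit_depth, spacing=spacing, source_id=path.stem)
        if "WindowCenter" in ds and "WindowWidth" in ds:
            center = ds.WindowCenter
            width = ds.WindowWidth
            if isinstance(center, pydicom.multival.MultiValue):
                center, width = center[0], width[0]
            grid.voi = VOIWindow(float(center), float(width))
        else:
            grid.voi = None
        return grid

    if format in ("png", "pgm"):
        img = Image.open(path)
        arr = np.asarray(img)
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = np.asarray(img.convert("L"))
        bit_depth = 16 if arr.dtype.itemsize > 1 else 8
        grid = ImageGrid(arr, bit_depth=bit_depth, source_id=path.stem)
        grid.voi = None
        return grid

    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Contrast enhancement
# ---------------------------------------------------------------------------

def apply_voi_lut(
    image: ImageGrid | np.ndarray,
    voi: VOIWindow | str | None = None,
    max_out: float | None = None,
) -> ImageGrid:
    """Map intensities through a VOI window / LUT.

    ``voi`` may be a :class:`VOIWindow` (linear DICOM windowing),
    ``"identity"`` (no-op), or ``None`` — the fallback policy, a
    full-range linear min-max window. The mapping is monotonically
    non-decreasing and the output is normalized to ``[0, max_out]``
    (default: the input's bit-depth ceiling).
    """
    grid = image if isinstance(image, ImageGrid) else ImageGrid(np.asarray(image), bit_depth=16)
    x = grid.pixels.astype(np.float64)
    top = float(2**grid.bit_depth - 1) if max_out is None else float(max_out)

    if voi == "identity":
        out = x
    else:
        if voi is None:
            voi = getattr(grid, "voi", None)
        if voi is None:
            lo, hi = float(x.min()), float(x.max())
            if hi == lo:  # constant image: nothing to window
                out = x
            else:
                out = (x - lo) / (hi - lo) * top
        else:
            if not isinstance(voi, VOIWindow):
                raise TypeError(f"voi must be VOIWindow, 'identity' or None, got {type(voi)}")
            c, w = voi.center, voi.width
            if w == 1:
                out = np.where(x > c - 0.5, top, 0.0)
            else:
                # DICOM linear VOI function, output scaled to [0, top].
                out = ((x - (c - 0.5)) / (w - 1.0) + 0.5)
                out = np.clip(out, 0.0, 1.0) * top

    result = ImageGrid(out, bit_depth=grid.bit_depth, spacing=grid.spacing,
                       source_id=grid.source_id)
    if np.nanmax(out, initial=0) > 2**grid.bit_depth - 1:  # pragma: no cover
        raise AssertionError("windowed output escaped the declared range")
    return result


# ---------------------------------------------------------------------------
# Binarization and island analysis
# ---------------------------------------------------------------------------

def binarize(image: ImageGrid | np.ndarray, policy: str = "otsu",
             threshold: float | None = None) -> BinaryMask:
    """Threshold an image into a foreground mask: ``pixel > t``.

    ``policy="otsu"`` picks the threshold maximizing between-class
    variance; ``policy="fixed"`` uses ``threshold``. A constant image
    under Otsu yields an all-zero mask with a warning rather than
    aborting a batch run.
    """
    x = as_pixels(image)
    if x.size == 0:
        raise ValueError("cannot binarize an empty image")
    if policy == "fixed":
        if threshold is None:
            raise ValueError("fixed policy requires a threshold")
        t = float(threshold)
    elif policy == "otsu":
        if np.all(x == x.flat[0]):
            warnings.warn("constant image under Otsu: emitting an all-zero mask",
                          stacklevel=2)
            return BinaryMask(np.zeros_like(x, dtype=np.uint8),
                              source_id=getattr(image, "source_id", ""))
        t = float(threshold_otsu(x))
    else:
        raise ValueError(f"unknown binarization policy {policy!r}")
    return BinaryMask((x > t).astype(np.uint8), source_id=getattr(image, "source_id", ""))


def connected_components(mask: BinaryMask | np.ndarray, connectivity: int = 4) -> IslandSet:
    """Label maximal connected foreground islands (edge-sharing neighbours).

    Only 4-connectivity is supported: two pixels belong to the same island
    iff they are linked by a chain of horizontal/vertical adjacencies.
    """
    if connectivity != 4:
        raise ValueError("only 4-connectivity is supported")
    m = as_pixels(mask)
    labels, n = ndimage.label(m, structure=FOUR_CONNECTIVITY)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return IslandSet(labels=labels, areas=areas,
                     source_id=getattr(mask, "source_id", ""))


def select_breast_region(
    islands: IslandSet, image: ImageGrid | np.ndarray | None = None
) -> tuple[BinaryMask, list[AnnotationRecord]]:
    """Keep the maximum-area island (the breast); record all the others.

    Ties on area break to the lowest island label, i.e. raster-scan order
    of first occurrence. Raises if the island set is empty.
    """
    if islands.n_islands == 0:
        raise ValueError("no foreground found: island set is empty")
    best = int(np.argmax(islands.areas)) + 1  # argmax -> lowest label on ties
    breast = BinaryMask((islands.labels == best).astype(np.uint8),
                        source_id=islands.source_id)
    records = _records_for(islands, exclude=best, image=image)
    return breast, records


def _records_for(islands: IslandSet, exclude: int | None,
                 image: ImageGrid | np.ndarray | None) -> list[AnnotationRecord]:
    pix = as_pixels(image) if image is not None else None
    slices = ndimage.find_objects(islands.labels)
    records = []
    for k, sl in enumerate(slices, start=1):
        if k == exclude or sl is None:
            continue
        member = islands.labels[sl] == k
        mean_int = float(pix[sl][member].mean()) if pix is not None else math.nan
        records.append(AnnotationRecord(
            island_id=k,
            area_px=int(islands.areas[k - 1]),
            xmin=sl[1].start, ymin=sl[0].start,
            xmax=sl[1].stop - 1, ymax=sl[0].stop - 1,
            mean_intensity=mean_int,
        ))
    return records


def strip_annotations(
    image: ImageGrid,
    breast: BinaryMask,
    foreground: BinaryMask | None = None,
) -> tuple[ImageGrid, list[AnnotationRecord]]:
    """Zero every pixel outside the breast mask; record what was removed.

    Pixels inside the breast mask are preserved bit-for-bit. Removed
    islands are the 4-connected components of the foreground lying outside
    the breast mask; ``foreground`` defaults to an Otsu binarization of
    the image.
    """
    x = as_pixels(image)
    b = as_pixels(breast)
    if x.shape != b.shape:
        raise ValueError(f"shape mismatch: image {x.shape} vs breast mask {b.shape}")
    if foreground is None:
        foreground = binarize(image)
    leftovers = connected_components(as_pixels(foreground) & (b == 0))
    records = _records_for(leftovers, exclude=None, image=image)
    cleaned = np.where(b == 1, x, 0)
    grid = ImageGrid(cleaned, bit_depth=getattr(image, "bit_depth", 16),
                     spacing=getattr(image, "spacing", None),
                     source_id=getattr(image, "source_id", ""))
    return grid, records


def write_annotation_records(records: list[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_CSV_HEADER)
        for r in records:
            writer.writerow([r.island_id, r.area_px, r.xmin, r.ymin, r.xmax, r.ymax,
                             f"{r.mean_intensity:.3f}"])


# ---------------------------------------------------------------------------
# Whole-image pipeline
# ---------------------------------------------------------------------------

def preprocess_mammogram(
    image: ImageGrid,
    voi: VOIWindow | str | None = None,
    binarize_policy: str = "otsu",
    fixed_threshold: float | None = None,
    enhance_first: bool = False,
) -> tuple[ImageGrid, BinaryMask, list[AnnotationRecord]]:
    """Run mask → breast segmentation → VOI-LUT enhancement on one image.

    With ``enhance_first=True`` the contrast step runs before
    binarization instead (the pipeline order is configurable because
    either order yields the same three-class restructuring).

    Returns the cleaned+enhanced image, the breast binary mask, and the
    records of the removed annotation islands.
    """
    work = apply_voi_lut(image, voi) if enhance_first else image
    fg = binarize(work, policy=binarize_policy, threshold=fixed_threshold)
    islands = connected_components(fg)
    breast, _ = select_breast_region(islands, image=work)
    cleaned, records = strip_annotations(work, breast, foreground=fg)
    if not enhance_first:
        cleaned = apply_voi_lut(cleaned, voi)
    return cleaned, breast, records
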