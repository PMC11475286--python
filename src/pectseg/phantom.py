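"""Synthetic MLO-like mammogram phantoms with exact 3-class ground truth.

The generator emulates the geometry of a mediolateral-oblique view: a
large breast region modelled as a half-ellipse pressed against the
chest-wall edge of the frame, a bright pectoral-muscle wedge modelled as
a triangle anchored in the adjacent image corner, and a handful of small
high-intensity annotation islands (machine labels / radiologist marks)
placed in the background. Per-class mean intensities follow the ordering
muscle > breast > background, since it is the muscle's intensity profile
that interferes with downstream tissue analysis.

Class proportions are controlled analytically: the wedge legs are solved
from the requested muscle fraction, and the breast semi-axis is found by
bisection on the rasterized half-ellipse so that emitted proportions land
within a small discretization error of the request.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .core import BACKGROUND, BREAST, MUSCLE, ImageGrid, LabelMask

__all__ = [
    "PhantomSpec",
    "Annotation",
    "generate_phantom",
    "generate_dataset",
    "save_phantom",
    "write_annotations_csv",
    "write_synthetic_dicom",
]

#: Aspect ratio (vertical leg / horizontal leg) of the pectoral wedge.
_WEDGE_ASPECT = 1.6
#: Vertical semi-axis of the breast half-ellipse, as a fraction of image height.
_ELLIPSE_AY = 0.48
#: Clearance (pixels) between an annotation island and the breast/muscle region.
_ANNOTATION_MARGIN = 2.0


@dataclass(frozen=True)
class Annotation:
    """A planted bright artifact island (class 0 in the ground truth)."""

    x: int
    y: int
    radius: int
    kind: str = "synthetic_marker"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters for one synthetic mammogram.

    Default class proportions (breast 0.60, muscle 0.08, background 0.32)
    mirror the pixel budget of a typical MLO mammogram in which the breast
    dominates the frame and the pectoral wedge is the rarest class.
    """

    image_size: tuple[int, int] = (256, 256)  # (rows, cols)
    breast_fraction: float = 0.60
    muscle_fraction: float = 0.08
    corner: str = "upper-left"  # anchor of the pectoral wedge
    n_annotations: int = 3
    annotation_size_range: tuple[int, int] = (2, 5)  # radius, pixels
    intensity_means: tuple[float, float, float] = (30.0, 120.0, 200.0)  # bg, breast, muscle
    annotation_intensity: float = 245.0
    noise_sd: float = 8.0
    bit_depth: int = 8
    seed: int | tuple = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        for name, frac in (("breast_fraction", self.breast_fraction),
                           ("muscle_fraction", self.muscle_fraction)):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {frac}")
        if self.breast_fraction + self.muscle_fraction >= 1.0:
            raise ValueError("breast_fraction + muscle_fraction must be < 1")
        if self.corner not in ("upper-left", "upper-right"):
            raise ValueError(f"corner must be 'upper-left' or 'upper-right', got {self.corner!r}")
        if self.n_annotations < 0:
            raise ValueError("n_annotations must be >= 0")
        lo, hi = self.annotation_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad annotation_size_range {self.annotation_size_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bg, br, mu = self.intensity_means
        if not (mu > br > bg >= 0):
            raise ValueError("intensity_means must satisfy muscle > breast > background >= 0")


class InfeasibleGeometryError(ValueError):
    """Requested class fractions are unreachable at the given image size."""


def _wedge_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the pectoral wedge: a right triangle anchored at spec.corner."""
    h, w = spec.image_size
    # Legs solved so that the triangle area equals the muscle pixel budget.
    leg_x = np.sqrt(2.0 * spec.muscle_fraction * h * w / _WEDGE_ASPECT)
    leg_y = _WEDGE_ASPECT * leg_x
    if leg_x > w or leg_y > h:
        raise InfeasibleGeometryError(
            f"muscle_fraction={spec.muscle_fraction} needs wedge legs "
            f"({leg_y:.0f}, {leg_x:.0f}) exceeding image {spec.image_size}"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    xx = xx + 0.5  # pixel centers
    yy = yy + 0.5
    if spec.corner == "upper-right":
        xx = w - xx
    return (xx / leg_x + yy / leg_y) < 1.0


def _ellipse_mask(spec: PhantomSpec, bx: float) -> np.ndarray:
    """Half-ellipse against the chest-wall edge (same side as the wedge)."""
    h, w = spec.image_size
    ay = _ELLIPSE_AY * h
    yy, xx = np.mgrid[0:h, 0:w]
    xx = xx + 0.5
    yy = yy + 0.5
    if spec.corner == "upper-right":
        xx = w - xx
    return (xx / bx) ** 2 + ((yy - h / 2.0) / ay) ** 2 <= 1.0


def _solve_label_mask(spec: PhantomSpec) -> np.ndarray:
    """Build the {0,1,2} label raster hitting the requested class fractions."""
    h, w = spec.image_size
    total = h * w
    wedge = _wedge_mask(spec)
    target = int(round(spec.breast_fraction * total))

    def breast_count(bx: float) -> int:
        return int(np.count_nonzero(_ellipse_mask(spec, bx) & ~wedge))

    lo, hi = 1e-3, float(w)
    if breast_count(hi) < target:
        raise InfeasibleGeometryError(
            f"breast_fraction={spec.breast_fraction} unreachable: half-ellipse at "
            f"full width covers only {breast_count(hi) / total:.3f} of the frame"
        )
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if breast_count(mid) < target:
            lo = mid
        else:
            hi = mid
    ellipse = _ellipse_mask(spec, hi)

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[ellipse] = BREAST
    mask[wedge] = MUSCLE

    fractions = np.bincount(mask.ravel(), minlength=3) / total
    request = np.array([
        1.0 - spec.breast_fraction - spec.muscle_fraction,
        spec.breast_fraction,
        spec.muscle_fraction,
    ])
    if np.max(np.abs(fractions - request)) > 0.03:
        raise InfeasibleGeometryError(
            f"class fractions {fractions.round(4)} deviate from request "
            f"{request.round(4)} by more than 3 percentage points"
        )
    return mask


def _place_annotations(mask: np.ndarray, spec: PhantomSpec,
                       rng: np.random.Generator) -> list[Annotation]:
    """Sample non-overlapping bright islands strictly inside background."""
    if spec.n_annotations == 0:
        return []
    h, w = mask.shape
    # Distance from each background pixel to the nearest foreground pixel.
    dist = ndimage.distance_transform_edt(mask == BACKGROUND)
    lo, hi = spec.annotation_size_range
    placed: list[Annotation] = []
    attempts = 0
    while len(placed) < spec.n_annotations:
        attempts += 1
        if attempts > 500:
            raise InfeasibleGeometryError(
                f"could not place {spec.n_annotations} annotation islands of radius "
                f"{spec.annotation_size_range} in the background region"
            )
        r = int(rng.integers(lo, hi + 1))
        eligible = dist >= (r + _ANNOTATION_MARGIN)
        eligible[: r + 1, :] = False
        eligible[h - r - 1:, :] = False
        eligible[:, : r + 1] = False
        eligible[:, w - r - 1:] = False
        for a in placed:
            yy, xx = np.ogrid[0:h, 0:w]
            too_close = (yy - a.y) ** 2 + (xx - a.x) ** 2 <= (a.radius + r + 2) ** 2
            eligible &= ~too_close
        coords = np.flatnonzero(eligible)
        if coords.size == 0:
            continue
        pick = int(coords[rng.integers(coords.size)])
        placed.append(Annotation(x=pick % w, y=pick // w, radius=r))
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[ImageGrid, LabelMask, list[Annotation]]:
    """Generate one synthetic mammogram, its ground truth, and its artifacts.

    Returns
    -------
    image : ImageGrid
        Grayscale raster with per-class mean intensity plus Gaussian noise;
        annotation islands rendered bright, clipped to the declared bit depth.
    mask : LabelMask
        Exact {0,1,2} ground truth. Annotation pixels remain class 0.
    annotations : list of Annotation
        Centers, radii and kinds of the planted artifact islands.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = _solve_label_mask(spec)
    annotations = _place_annotations(mask, spec, rng)

    means = np.asarray(spec.intensity_means, dtype=np.float64)
    image = means[mask] + rng.normal(0.0, spec.noise_sd, size=mask.shape)
    h, w = mask.shape
    yy, xx = np.ogrid[0:h, 0:w]
    for a in annotations:
        disk = (yy - a.y) ** 2 + (xx - a.x) ** 2 <= a.radius**2
        image[disk] = spec.annotation_intensity + rng.normal(
            0.0, spec.noise_sd, size=int(disk.sum())
        )
    image = np.clip(image, 0.0, 2**spec.bit_depth - 1).astype(np.float32)

    sid = f"phantom-{spec.seed}"
    return (
        ImageGrid(image, bit_depth=spec.bit_depth, source_id=sid),
        LabelMask(mask, source_id=sid),
        annotations,
    )


def generate_dataset(
    n: int, spec: PhantomSpec | None = None, seed: int | None = None
) -> list[tuple[ImageGrid, LabelMask]]:
    """Generate ``n`` phantom image/mask pairs with counter-derived seeds.

    Each item ``i`` is produced from the seed pair ``(master, i)`` so any
    item is reproducible independently of the rest of the dataset.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec = spec or PhantomSpec()
    master = spec.seed if seed is None else seed
    if not np.isscalar(master):
        raise ValueError("master seed must be a scalar integer")
    pairs = []
    for i in range(n):
        image, mask, _ = generate_phantom(replace(spec, seed=(int(master), i)))
        image.source_id = f"phantom-{master}-{i:04d}"
        mask.source_id = image.source_id
        pairs.append((image, mask))
    return pairs


# ---------------------------------------------------------------------------
# On-disk export: grayscale PNG images, raw-value mask PNGs, annotation CSVs,
# and (optionally) minimal DICOM files for exercising the DICOM reader.
# ---------------------------------------------------------------------------

def write_annotations_csv(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "radius", "kind"])
        for a in annotations:
            writer.writerow([a.x, a.y, a.radius, a.kind])


def save_phantom(
    outdir: str | Path,
    stem: str,
    image: ImageGrid,
    mask: LabelMask,
    annotations: list[Annotation] | None = None,
) -> dict[str, Path]:
    """Write ``<stem>.png``, ``<stem>_mask.png`` and ``<stem>_annotations.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if image.bit_depth <= 8:
        arr = np.round(image.pixels).astype(np.uint8)
        img = Image.fromarray(arr, mode="L")
    else:
        arr = np.round(image.pixels).astype(np.uint16)
        img = Image.fromarray(arr, mode="I;16")
    paths["image"] = outdir / f"{stem}.png"
    img.save(paths["image"])
    paths["mask"] = outdir / f"{stem}_mask.png"
    Image.fromarray(mask.pixels, mode="L").save(paths["mask"])
    if annotations is not None:
        paths["annotations"] = outdir / f"{stem}_annotations.csv"
        write_annotations_csv(annotations, paths["annotations"])
    return paths


def write_synthetic_dicom(
    path: str | Path,
    pixels: np.ndarray,
    spacing: tuple[float, float] | None = None,
    window: tuple[float, float] | None = None,
) -> Path:
    """Write a minimal synthetic secondary-capture DICOM around ``pixels``.

    Intended for exercising the DICOM ingestion path; carries only pixel
    data plus the optional PixelSpacing and linear VOI window elements.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("pixels must be 2-D")
    arr = np.round(pixels).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    if spacing is not None:
        ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
    if window is not None:
        ds.WindowCenter = str(window[0])
        ds.WindowWidth = str(window[1])
    ds.save_as(str(path), enforce_file_format=True)
    return Path(path)
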