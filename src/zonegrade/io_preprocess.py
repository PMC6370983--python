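"""Image ingestion, in-plane resampling, intensity normalization and ROI extraction.

The analysis operates on single axial 2-D slices: high-b-value diffusion
(b = 800) for peripheral-zone lesions and T2-weighted images for lesions in
the transitional zone / anterior fibromuscular stroma. Slices are resampled
to a common 0.5 mm in-plane grid, T2W intensities are z-score normalized to
remove inter-patient scaling, and a square 61 x 61-pixel fragment centered
on the reported lesion coordinate is cut out for feature extraction. No
co-registration is performed between sequences; they are never combined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageSlice2D",
    "LesionRecord",
    "ROIFragment",
    "world_to_pixel",
    "pixel_to_world",
    "resample_inplane",
    "zscore_normalize",
    "extract_roi",
    "read_lesion_records",
    "write_lesion_records",
    "read_image",
]

MODALITIES = ("T2W", "DWI_B800")
ZONES = ("PZ", "TZ", "AFS")

#: default ROI edge length in pixels (odd, lesion-centered)
DEFAULT_ROI_SIZE = 61
#: default in-plane target spacing in mm
DEFAULT_SPACING = 0.5


@dataclass(frozen=True)
class ImageSlice2D:
    """A 2-D grayscale slice with physical pixel spacing.

    Pixel (i, j) sits at world coordinate ``origin + (i*spacing_row,
    j*spacing_col)`` in mm, row-major, 0-based.
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    origin: tuple[float, float] = (0.0, 0.0)
    modality: str = "T2W"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: identity, prostatic zone, center location and Grade Group.

    ``center`` is (row, col); ``center_in_world`` says whether it is in mm
    (world coordinates) or already a pixel index.
    """

    patient_id: str
    lesion_id: str
    zone: str
    center: tuple[float, float]
    gg: int
    center_in_world: bool = True
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")
        if self.gg not in (1, 2, 3, 4, 5):
            raise ValueError(f"Grade Group must be in 1..5, got {self.gg!r}")


@dataclass(frozen=True)
class ROIFragment:
    """A 61 x 61 lesion-centered fragment, the unit of feature extraction."""

    pixels: np.ndarray
    modality: str = "T2W"
    patient_id: str = ""
    lesion_id: str = ""
    size: int = field(init=False, default=DEFAULT_ROI_SIZE)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("fragment must be square")
        if not np.all(np.isfinite(px)):
            raise ValueError("fragment pixels must be finite")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "size", px.shape[0])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def world_to_pixel(sl: ImageSlice2D, point: tuple[float, float],
                   lesion: str = "") -> tuple[int, int]:
    """Map a world-mm point to the nearest 0-based (row, col) pixel index.

    Raises ``IndexError`` naming the lesion if the index falls outside the
    grid.
    """
    r = _round_half_up((point[0] - sl.origin[0]) / sl.spacing_row)
    c = _round_half_up((point[1] - sl.origin[1]) / sl.spacing_col)
    nr, nc = sl.shape
    if not (0 <= r < nr and 0 <= c < nc):
        who = f" for lesion {lesion!r}" if lesion else ""
        raise IndexError(
            f"world point {point} maps to pixel ({r}, {c}) outside the "
            f"{nr}x{nc} grid{who}")
    return r, c


def pixel_to_world(sl: ImageSlice2D, index: tuple[int, int]) -> tuple[float, float]:
    """Inverse of :func:`world_to_pixel` for exact grid indices."""
    return (sl.origin[0] + index[0] * sl.spacing_row,
            sl.origin[1] + index[1] * sl.spacing_col)


def resample_inplane(sl: ImageSlice2D,
                     target_spacing: float = DEFAULT_SPACING) -> ImageSlice2D:
    """Bilinearly resample a slice to an isotropic in-plane spacing.

    The output covers the same physical field of view: the new dimension is
    ``round(old_dim * old_spacing / target)``. Edge samples replicate the
    border, so constant images are reproduced exactly and a round trip back
    to the original spacing is exact for constants.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    nr, nc = sl.shape
    new_nr = max(1, _round_half_up(nr * sl.spacing_row / target_spacing))
    new_nc = max(1, _round_half_up(nc * sl.spacing_col / target_spacing))
    rows = np.arange(new_nr) * target_spacing / sl.spacing_row
    cols = np.arange(new_nc) * target_spacing / sl.spacing_col
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(sl.pixels, grid, order=1, mode="nearest")
    return replace(sl, pixels=out, spacing_row=target_spacing,
                   spacing_col=target_spacing)


def zscore_normalize(sl: ImageSlice2D) -> ImageSlice2D:
    """Standardize slice intensities to mean 0, population SD 1.

    Intended for T2W slices, whose arbitrary scaling varies between patients;
    diffusion intensities are left untouched by the pipeline. A constant
    slice has no scale and is rejected.
    """
    mu = float(sl.pixels.mean())
    sd = float(sl.pixels.std())
    if sd == 0:
        raise ValueError("cannot z-score a constant image (zero variance)")
    return replace(sl, pixels=(sl.pixels - mu) / sd)


def extract_roi(sl: ImageSlice2D, center: tuple[int, int],
                size: int = DEFAULT_ROI_SIZE, *, pad: bool = False,
                modality: str | None = None, patient_id: str = "",
                lesion_id: str = "") -> ROIFragment:
    """Cut the ``size`` x ``size`` window centered on a pixel index.

    Offsets run -(size-1)/2 .. +(size-1)/2 in each axis. If the window
    exceeds the grid, the default is a hard error naming the lesion;
    ``pad=True`` replicates edge pixels instead.
    """
    if size % 2 != 1 or size < 1:
        raise ValueError("ROI size must be a positive odd integer")
    nr, nc = sl.shape
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < nr and 0 <= c < nc):
        raise IndexError(f"ROI center ({r}, {c}) outside the {nr}x{nc} grid"
                         + (f" for lesion {lesion_id!r}" if lesion_id else ""))
    h = (size - 1) // 2
    r0, r1, c0, c1 = r - h, r + h + 1, c - h, c + h + 1
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
        if not pad:
            who = f" for lesion {lesion_id!r}" if lesion_id else ""
            raise IndexError(
                f"{size}x{size} ROI at ({r}, {c}) exceeds the {nr}x{nc} "
                f"grid{who}; enable padding to replicate edges")
        pr0, pc0 = max(0, -r0), max(0, -c0)
        pr1, pc1 = max(0, r1 - nr), max(0, c1 - nc)
        padded = np.pad(sl.pixels, ((pr0, pr1), (pc0, pc1)), mode="edge")
        window = padded[r0 + pr0:r1 + pr0, c0 + pc0:c1 + pc0]
    else:
        window = sl.pixels[r0:r1, c0:c1]
    return ROIFragment(pixels=window.copy(),
                       modality=modality or sl.modality,
                       patient_id=patient_id, lesion_id=lesion_id)


# ---------------------------------------------------------------------------
# Tabular and image IO

LESION_CSV_HEADER = ["patient_id", "lesion_id", "zone", "center_row_mm",
                     "center_col_mm", "slice_index", "gg"]


def read_lesion_records(path: str | Path) -> list[LesionRecord]:
    """Read the lesion-record CSV (world-mm centers)."""
    path = Path(path)
    records: list[LesionRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(LESION_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for ln, row in enumerate(reader, start=2):
            try:
                records.append(LesionRecord(
                    patient_id=row["patient_id"],
                    lesion_id=row["lesion_id"],
                    zone=row["zone"],
                    center=(float(row["center_row_mm"]),
                            float(row["center_col_mm"])),
                    gg=int(row["gg"]),
                    slice_index=int(row["slice_index"] or 0),
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {ln}: {exc}") from exc
    return records


def write_lesion_records(records: list[LesionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LESION_CSV_HEADER)
        for r in records:
            w.writerow([r.patient_id, r.lesion_id, r.zone,
                        f"{r.center[0]:.6g}", f"{r.center[1]:.6g}",
                        r.slice_index, r.gg])


def read_image(path: str | Path, *, modality: str = "T2W",
               spacing: tuple[float, float] | None = None,
               slice_index: int = 0) -> ImageSlice2D:
    """Read a single grayscale slice from DICOM, NIfTI or 16-bit PNG.

    DICOM and NIfTI carry their own spacing; PNG requires ``spacing`` to be
    supplied (sidecar/config). For NIfTI volumes one axial slice is selected
    by ``slice_index``.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(str(path))
        px = ds.pixel_array.astype(float)
        if px.ndim != 2:
            raise ValueError(f"{path}: expected a single-frame DICOM")
        sp = getattr(ds, "PixelSpacing", None)
        if sp is None:
            if spacing is None:
                raise ValueError(f"{path}: no PixelSpacing and none supplied")
            sp = spacing
        return ImageSlice2D(px, float(sp[0]), float(sp[1]), modality=modality)
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim == 3:
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"{path}: unsupported NIfTI dimensionality")
        zooms = img.header.get_zooms()
        return ImageSlice2D(data, float(zooms[0]), float(zooms[1]),
                            modality=modality)
    if suffix.endswith(".png"):
        import imageio.v3 as iio

        px = iio.imread(str(path)).astype(float)
        if px.ndim != 2:
            raise ValueError(f"{path}: expected grayscale PNG")
        if spacing is None:
            raise ValueError(f"{path}: PNG requires explicit pixel spacing")
        return ImageSlice2D(px, float(spacing[0]), float(spacing[1]),
                            modality=modality)
    raise ValueError(f"{path}: unsupported image format {suffix!r}")
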