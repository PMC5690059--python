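"""Reading and calibrating axial CT series.

CT pixel data is stored either as raw scanner counts ("CT data") or directly
in Hounsfield units (HU).  The linear rescale

    HU = stored * slope + intercept

with the slope/intercept taken from the DICOM rescale tags (0028,1053) /
(0028,1052) maps stored values onto the HU scale (water 0, air -1000,
scale floor -1024).  This module produces a :class:`CTVolume` — a calibrated
HU volume with physical pixel spacing — from either a DICOM series or a
plain array container with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

HU_FLOOR = -1024.0
HU_CEIL = 3071.0

#: default rescale applied when a series carries no rescale tags
DEFAULT_SLOPE = 1.0
DEFAULT_INTERCEPT = -1024.0

RAW_META_NAME = "meta.json"
RAW_ARRAY_NAME = "volume.npy"


class ImageIOError(RuntimeError):
    """Raised when a series cannot be read or is inconsistent."""


@dataclass(frozen=True)
class CalibrationMeta:
    """Linear rescale mapping stored pixel values to Hounsfield units."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("calibration slope/intercept must be finite")
        if self.slope == 0:
            raise ValueError("rescale slope must be non-zero")


#: calibration of data already expressed in HU (identity transform)
ALREADY_HU = CalibrationMeta(slope=1.0, intercept=0.0)


@dataclass
class CTVolume:
    """Calibrated 3D HU volume.

    Attributes
    ----------
    hu : (n_slices, rows, cols) float array in Hounsfield units.
    pixel_spacing : (row, col) in-plane spacing in mm/pixel.
    slice_positions : per-slice longitudinal coordinate in mm, monotone.
    """

    hu: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.hu.ndim}")
        rs, cs = self.pixel_spacing
        if not (rs > 0 and cs > 0):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(rs), float(cs))
        if self.slice_positions is None:
            self.slice_positions = np.arange(self.hu.shape[0], dtype=float)
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.hu.shape[0],):
            raise ValueError("slice_positions length must match number of slices")
        d = np.diff(self.slice_positions)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("slice positions must be monotone along the axis")
        if np.any(self.hu > HU_CEIL):
            warnings.warn(
                f"HU values above {HU_CEIL:g} present (max {self.hu.max():.1f}); "
                "metal or calibration artifact suspected",
                stacklevel=2,
            )
        if np.any(self.hu < HU_FLOOR):
            # sub-floor values arise from noise around the air level; clamp to
            # the physical floor of the scale rather than reject the series
            warnings.warn(
                f"HU values below {HU_FLOOR:g} clamped to the scale floor",
                stacklevel=2,
            )
            self.hu = np.maximum(self.hu, HU_FLOOR)

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0


def to_hu(raw, cal: CalibrationMeta):
    """Convert stored pixel values to Hounsfield units: HU = raw*S + I.

    Works element-wise on arrays; rejects non-finite input.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite stored pixel values cannot be calibrated")
    out = raw * cal.slope + cal.intercept
    return out if out.ndim else float(out)


def from_hu(hu, cal: CalibrationMeta):
    """Inverse of :func:`to_hu`: stored = (HU - I)/S."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU values cannot be inverted")
    out = (hu - cal.intercept) / cal.slope
    return out if out.ndim else float(out)


def load_series(path) -> CTVolume:
    """Load a CT series from ``path`` and return a calibrated :class:`CTVolume`.

    ``path`` may be a directory containing a DICOM series, or a directory
    containing the plain array container (``volume.npy`` + ``meta.json``)
    written by :func:`save_raw`.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such path: {path}")
    if path.is_dir() and (path / RAW_META_NAME).exists():
        return _load_raw(path)
    return _load_dicom(path)


# ---------------------------------------------------------------------------
# plain array container: volume.npy (stored values) + meta.json sidecar
# ---------------------------------------------------------------------------

def _load_raw(path: Path) -> CTVolume:
    meta = json.loads((path / RAW_META_NAME).read_text())
    arr = np.load(path / RAW_ARRAY_NAME)
    if "pixel_spacing" not in meta:
        raise ImageIOError(f"{path}: meta.json lacks pixel_spacing")
    spacing = tuple(float(v) for v in meta["pixel_spacing"])
    if "slope" in meta or "intercept" in meta:
        cal = CalibrationMeta(
            slope=float(meta.get("slope", DEFAULT_SLOPE)),
            intercept=float(meta.get("intercept", DEFAULT_INTERCEPT)),
        )
    else:
        logger.warning("%s: no rescale metadata; assuming S=%g, I=%g",
                       path, DEFAULT_SLOPE, DEFAULT_INTERCEPT)
        cal = CalibrationMeta()
    positions = meta.get("slice_positions")
    if positions is not None:
        positions = np.asarray(positions, dtype=float)
        order = np.argsort(positions)
        arr = arr[order]
        positions = positions[order]
    return CTVolume(to_hu(arr, cal), spacing, positions)


def save_raw(path, stored: np.ndarray, pixel_spacing, cal: CalibrationMeta,
             slice_positions=None) -> None:
    """Write a stored-value volume plus JSON sidecar readable by load_series."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / RAW_ARRAY_NAME, np.asarray(stored))
    meta = {
        "pixel_spacing": list(pixel_spacing),
        "slope": cal.slope,
        "intercept": cal.intercept,
    }
    if slice_positions is not None:
        meta["slice_positions"] = [float(z) for z in slice_positions]
    (path / RAW_META_NAME).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _load_dicom(path: Path) -> CTVolume:
    import pydicom
    from pydicom.errors import InvalidDicomError

    files = sorted(p for p in path.iterdir() if p.is_file()) if path.is_dir() else [path]
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except (InvalidDicomError, Exception) as exc:  # noqa: BLE001 - skip non-image files
            logger.debug("skipping %s: %s", f, exc)
    datasets = [ds for ds in datasets if hasattr(ds, "PixelData")]
    if not datasets:
        raise ImageIOError(f"no images found under {path}")

    # sort by longitudinal position when present, instance order otherwise
    if all(hasattr(ds, "ImagePositionPatient") for ds in datasets):
        datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        positions = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        logger.info("slice order from ImagePositionPatient")
    elif all(hasattr(ds, "SliceLocation") for ds in datasets):
        datasets.sort(key=lambda ds: float(ds.SliceLocation))
        positions = np.array([float(ds.SliceLocation) for ds in datasets])
        logger.info("slice order from SliceLocation")
    else:
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        positions = None
        logger.warning("no positional metadata; using instance/file order")

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise ImageIOError(f"inconsistent in-plane dimensions across slices: {shapes}")

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ImageIOError("series lacks PixelSpacing metadata")
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))

    slices = []
    for ds in datasets:
        if hasattr(ds, "RescaleSlope") and hasattr(ds, "RescaleIntercept"):
            cal = CalibrationMeta(float(ds.RescaleSlope), float(ds.RescaleIntercept))
        else:
            logger.warning("missing rescale tags; defaulting to S=%g, I=%g",
                           DEFAULT_SLOPE, DEFAULT_INTERCEPT)
            cal = CalibrationMeta()
        slices.append(to_hu(ds.pixel_array, cal))
    return CTVolume(np.stack(slices), spacing, positions)


def save_dicom_series(path, volume: CTVolume,
                      cal: CalibrationMeta = CalibrationMeta()) -> None:
    """Write ``volume`` as a minimal CT DICOM series (one file per slice)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    stored = np.round(from_hu(volume.hu, cal)).astype(np.int16)
    for i in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.slice_positions[i])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.RescaleSlope = cal.slope
        ds.RescaleIntercept = cal.intercept
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[i].tobytes()
        ds.save_as(path / f"slice_{i:04d}.dcm", enforce_file_format=True)
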