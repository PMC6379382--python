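"""Volume and mask I/O, HU calibration, and slice-thickness standardization.

All intensities are Hounsfield Units throughout the package. NIfTI is the
canonical on-disk format (via nibabel); DICOM series ingestion is available
only when ``pydicom`` is importable and always applies the rescale
slope/intercept so that in-memory voxels are HU.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

PHASES = ("precontrast", "pancreatic", "portal")

HU_MIN = -1024.0
HU_MAX = 4095.0

__all__ = [
    "PHASES",
    "CTVolume",
    "Mask3D",
    "GeometryError",
    "CalibrationError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_slices",
    "resample_mask",
]


class GeometryError(ValueError):
    """Raised when a volume/mask/ROI geometry contract is violated."""


class CalibrationError(ValueError):
    """Raised when DICOM data lacks the tags needed to convert to HU."""


def _affine_from_spacing(spacing: Sequence[float], origin: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


@dataclasses.dataclass
class CTVolume:
    """One contrast-phase 3D scalar image in HU with geometry.

    ``voxels`` is indexed ``[i, j, k]`` with ``k`` the slice (z) axis;
    ``affine`` maps 0-based voxel indices to world millimetres.
    """

    voxels: np.ndarray
    affine: np.ndarray
    phase: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D scalar grid, got ndim={self.voxels.ndim}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"voxel values [{lo:.1f}, {hi:.1f}] outside the HU range [{HU_MIN}, {HU_MAX}]"
            )
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {tuple(self.spacing)}")

    @property
    def spacing(self) -> np.ndarray:
        """(x, y, z) voxel spacing in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_geometry(self, other: "CTVolume | Mask3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclasses.dataclass
class Mask3D:
    """Boolean tumor segmentation sharing its volume's grid exactly."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if not self.voxels.any():
            raise ValueError("mask must contain at least one interior voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def same_geometry(self, other: "CTVolume | Mask3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


def _is_dicom_dir(path: Path) -> bool:
    return path.is_dir()


def _read_dicom_series(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise CalibrationError(
            "reading DICOM series requires the optional 'pydicom' dependency; "
            "convert the series to NIfTI instead"
        ) from exc

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    for ds in slices:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise CalibrationError(
                f"DICOM file {ds.filename} lacks RescaleSlope/RescaleIntercept; cannot convert to HU"
            )
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    hu = np.stack(
        [ds.pixel_array.T * float(ds.RescaleSlope) + float(ds.RescaleIntercept) for ds in slices],
        axis=-1,
    ).astype(np.float64)
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = [float(v) for v in first.ImagePositionPatient]
    return hu, _affine_from_spacing((dx, dy, dz), origin)


def read_volume(path: str | Path, phase: str) -> CTVolume:
    """Read a NIfTI file (or DICOM series directory) as an HU volume.

    DICOM stored values are always converted via rescale slope/intercept;
    missing rescale tags raise :class:`CalibrationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_dicom_dir(path):
        data, affine = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise GeometryError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
        affine = img.affine
    return CTVolume(voxels=data, affine=affine, phase=phase)


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; lossless round-trip with :func:`read_volume`."""
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return Mask3D(voxels=data != 0, affine=img.affine)


def write_mask(mask: Mask3D, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def resample_slices(vol: CTVolume, target_thickness: float = 5.0) -> CTVolume:
    """Standardize slice thickness by linear interpolation along z.

    The in-plane grid is untouched. Slice 0 keeps its world position, and the
    world z of output slice ``k`` is ``origin_z + k * target_thickness``.
    """
    if target_thickness <= 0:
        raise ValueError(f"target thickness must be positive, got {target_thickness}")
    sz = float(vol.spacing[2])
    nz = vol.shape[2]
    if abs(sz - target_thickness) < 1e-9:
        return CTVolume(vol.voxels.copy(), vol.affine.copy(), vol.phase)
    if nz == 1:
        raise GeometryError("cannot resample a single-slice volume to a different thickness")

    extent = (nz - 1) * sz
    n_out = int(np.floor(extent / target_thickness + 1e-9)) + 1
    if n_out < 1:
        raise GeometryError(
            f"target thickness {target_thickness} mm exceeds the z extent {extent} mm"
        )
    # fractional source index of each output slice center
    pos = np.arange(n_out) * (target_thickness / sz)
    lo = np.clip(np.floor(pos).astype(int), 0, nz - 2)
    frac = pos - lo
    data = vol.voxels.astype(np.float64)
    out = data[:, :, lo] * (1.0 - frac) + data[:, :, lo + 1] * frac

    affine = vol.affine.copy()
    affine[:3, 2] *= target_thickness / sz
    return CTVolume(out, affine, vol.phase)


def resample_mask(mask: Mask3D, target_thickness: float = 5.0, threshold: float = 0.5) -> Mask3D:
    """Resample a mask along z to match a resampled volume's grid.

    Linear interpolation of the indicator followed by thresholding; must be
    called explicitly (volumes and masks are never resampled implicitly).
    """
    carrier = CTVolume(mask.voxels.astype(np.float64), mask.affine, "pancreatic")
    res = resample_slices(carrier, target_thickness)
    return Mask3D(res.voxels >= threshold, res.affine)


# re-exported here because cohort tables are part of the I/O surface;
# implemented separately to keep the record types free of I/O imports
from .cohort_table import COHORT_COLUMNS, read_cohort_table, write_cohort_table  # noqa: E402

__all__ += ["COHORT_COLUMNS", "read_cohort_table", "write_cohort_table"]
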