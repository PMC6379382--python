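"""Circular-ROI HU measurement and enhancement/permeability ratio panel.

The six per-patient measurements are the mean HU inside circular ROIs placed
on the tumor (pancreatic + portal phase), the adjacent pancreatic parenchyma
(both phases), the aorta (pancreatic phase) and the portal vein (portal
phase). Ratios are dimensionless combinations of those means.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .imaging_io import CTVolume, GeometryError, PHASES

STRUCTURES = ("tumor", "pancreas", "aorta", "portal_vein")

#: Smallest admissible |denominator| in HU; enhanced vessels/parenchyma are
#: far above this, so anything smaller signals a data error.
DENOMINATOR_GUARD_HU = 1.0

MIN_ROI_VOXELS = 5

__all__ = [
    "STRUCTURES",
    "CircularROI",
    "MeasurementSet",
    "RatioPanel",
    "RatioDomainError",
    "roi_mean",
    "copy_roi_across_phases",
    "compute_ratios",
]


class RatioDomainError(ValueError):
    """A ratio denominator was too close to zero to be meaningful."""


@dataclasses.dataclass(frozen=True)
class CircularROI:
    """A 2D measurement disk on one slice, radius in millimetres."""

    structure: str
    phase: str
    slice_index: int
    center: tuple[float, float]  # (row, col) voxel coordinates
    radius_mm: float

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.radius_mm <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_mm}")

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "phase": self.phase,
            "slice_index": int(self.slice_index),
            "center_row": float(self.center[0]),
            "center_col": float(self.center[1]),
            "radius_mm": float(self.radius_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircularROI":
        return cls(
            structure=d["structure"],
            phase=d["phase"],
            slice_index=int(d["slice_index"]),
            center=(float(d["center_row"]), float(d["center_col"])),
            radius_mm=float(d["radius_mm"]),
        )


@dataclasses.dataclass(frozen=True)
class MeasurementSet:
    """The six ROI-mean HU values of one patient."""

    hu_tumor_art: float
    hu_tumor_port: float
    hu_pancreas_art: float
    hu_pancreas_port: float
    hu_aorta: float
    hu_portal: float

    FIELDS = (
        "hu_tumor_art",
        "hu_tumor_port",
        "hu_pancreas_art",
        "hu_pancreas_port",
        "hu_aorta",
        "hu_portal",
    )

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


@dataclasses.dataclass(frozen=True)
class RatioPanel:
    """The seven enhancement/permeability ratios.

    Satisfies the identity ``permeability_1 - permeability_2 ==
    2 * arterial`` exactly by construction.
    """

    tumor_parenchyma_ratio_1: float
    tumor_parenchyma_ratio_2: float
    tumor_arterial_ratio: float
    tumor_venous_ratio: float
    tumor_permeability_ratio_1: float
    tumor_permeability_ratio_2: float
    tumor_permeability_ratio_3: float

    FIELDS = (
        "tumor_parenchyma_ratio_1",
        "tumor_parenchyma_ratio_2",
        "tumor_arterial_ratio",
        "tumor_venous_ratio",
        "tumor_permeability_ratio_1",
        "tumor_permeability_ratio_2",
        "tumor_permeability_ratio_3",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


def disk_membership(
    shape: tuple[int, int], spacing: tuple[float, float], center: tuple[float, float], radius_mm: float
) -> np.ndarray:
    """Boolean in-plane membership: voxel centers within ``radius_mm`` (world mm)."""
    rows = (np.arange(shape[0]) - center[0]) * spacing[0]
    cols = (np.arange(shape[1]) - center[1]) * spacing[1]
    d2 = rows[:, None] ** 2 + cols[None, :] ** 2
    return d2 <= radius_mm**2


def roi_mean(vol: CTVolume, roi: CircularROI) -> float:
    """Arithmetic mean HU over the voxels whose centers fall inside the disk."""
    if not (0 <= roi.slice_index < vol.shape[2]):
        raise GeometryError(
            f"slice {roi.slice_index} outside volume with {vol.shape[2]} slices"
        )
    r, c = roi.center
    if not (0 <= r < vol.shape[0] and 0 <= c < vol.shape[1]):
        raise GeometryError(f"ROI center {roi.center} outside the {vol.shape[:2]} slice grid")
    sx, sy = float(vol.spacing[0]), float(vol.spacing[1])
    member = disk_membership(vol.shape[:2], (sx, sy), roi.center, roi.radius_mm)
    n = int(member.sum())
    if n < MIN_ROI_VOXELS:
        raise ValueError(
            f"ROI covers only {n} voxels (< {MIN_ROI_VOXELS}); too small for a meaningful mean"
        )
    return float(vol.voxels[:, :, roi.slice_index][member].mean())


def copy_roi_across_phases(
    roi: CircularROI,
    target_phase: str,
    source_vol: CTVolume | None = None,
    target_vol: CTVolume | None = None,
) -> CircularROI:
    """Propagate an ROI to another phase: same voxel coordinates, new label.

    No registration is performed; when both volumes are given, their
    geometries must match exactly or a :class:`GeometryError` is raised.
    """
    if target_phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {target_phase!r}")
    if source_vol is not None and target_vol is not None:
        if not source_vol.same_geometry(target_vol):
            raise GeometryError(
                "cannot copy ROI across phases with mismatched geometry "
                f"(shapes {source_vol.shape} vs {target_vol.shape}); no registration is performed"
            )
    return dataclasses.replace(roi, phase=target_phase)


def compute_ratios(m: MeasurementSet) -> RatioPanel:
    """Compute the seven enhancement/permeability ratios from one MeasurementSet."""
    guards = {
        "hu_pancreas_art": m.hu_pancreas_art,
        "hu_pancreas_port": m.hu_pancreas_port,
        "hu_aorta": m.hu_aorta,
        "hu_portal": m.hu_portal,
        "hu_tumor_port": m.hu_tumor_port,
    }
    for name, value in guards.items():
        if abs(value) < DENOMINATOR_GUARD_HU:
            raise RatioDomainError(
                f"denominator {name}={value} HU is below the {DENOMINATOR_GUARD_HU} HU guard"
            )
    tar = m.hu_tumor_art / m.hu_aorta
    p2 = (m.hu_tumor_port - m.hu_tumor_art) / m.hu_aorta
    # permeability_1 written as p2 + 2*tar so the linear identity holds exactly
    return RatioPanel(
        tumor_parenchyma_ratio_1=m.hu_tumor_art / m.hu_pancreas_art,
        tumor_parenchyma_ratio_2=m.hu_tumor_port / m.hu_pancreas_port,
        tumor_arterial_ratio=tar,
        tumor_venous_ratio=m.hu_tumor_port / m.hu_portal,
        tumor_permeability_ratio_1=p2 + 2.0 * tar,
        tumor_permeability_ratio_2=p2,
        tumor_permeability_ratio_3=m.hu_tumor_art / m.hu_tumor_port,
    )
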