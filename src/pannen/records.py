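"""Per-patient record types shared by the I/O, statistics and CLI layers."""

from __future__ import annotations

import dataclasses

from .roi_quant import MeasurementSet, RatioPanel
from .texture3d import TexturePanel

GRADES = ("G1", "G2", "G3")

MARGIN_LEVELS = ("sharp", "irregular")
ENHANCEMENT_LEVELS = ("hypo", "iso", "hyper")
PATTERN_LEVELS = ("homogeneous", "heterogeneous")

#: Boolean qualitative flags, in cohort-table column order.
BOOL_FLAGS = (
    "hypodense_areas",
    "calcifications",
    "mpd_dilation",
    "cbd_dilation",
    "vessel_involvement",
    "liver_metastases",
)

__all__ = [
    "GRADES",
    "MARGIN_LEVELS",
    "ENHANCEMENT_LEVELS",
    "PATTERN_LEVELS",
    "BOOL_FLAGS",
    "QualitativeRecord",
    "CohortRecord",
]


@dataclasses.dataclass(frozen=True)
class QualitativeRecord:
    """Radiologist-style categorical reading of one lesion.

    These are inputs (or phantom ground truth) — the package never derives
    them from images.
    """

    margins: str = "sharp"
    hypodense_areas: bool = False
    calcifications: bool = False
    mpd_dilation: bool = False  # main pancreatic duct > 3 mm
    cbd_dilation: bool = False  # common bile duct > 1 cm
    vessel_involvement: bool = False
    liver_metastases: bool = False
    enhancement_art: str = "hyper"
    enhancement_port: str = "hyper"
    enhancement_pattern: str = "homogeneous"

    def __post_init__(self) -> None:
        if self.margins not in MARGIN_LEVELS:
            raise ValueError(f"margins must be one of {MARGIN_LEVELS}, got {self.margins!r}")
        for name in ("enhancement_art", "enhancement_port"):
            if getattr(self, name) not in ENHANCEMENT_LEVELS:
                raise ValueError(
                    f"{name} must be one of {ENHANCEMENT_LEVELS}, got {getattr(self, name)!r}"
                )
        if self.enhancement_pattern not in PATTERN_LEVELS:
            raise ValueError(
                f"enhancement_pattern must be one of {PATTERN_LEVELS}, "
                f"got {self.enhancement_pattern!r}"
            )


@dataclasses.dataclass
class CohortRecord:
    """One row of the cohort table: grade, size, flags and feature panels."""

    patient_id: str
    grade: str
    size_mm: float
    qualitative: QualitativeRecord
    measurements: MeasurementSet | None = None
    ratios: RatioPanel | None = None
    texture: TexturePanel | None = None
    extraction_ok: bool = True
    error: str = ""

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
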