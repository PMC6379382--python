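"""Lossless CSV serialization of the per-patient cohort table.

Column order (fixed): patient_id, grade, size_mm, the 10 qualitative
columns, the 6 HU measurements, the 7 ratios, the 5 texture features plus
texture bookkeeping, then extraction status.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import BOOL_FLAGS, CohortRecord, QualitativeRecord
from .roi_quant import MeasurementSet, RatioPanel
from .texture3d import TexturePanel

__all__ = ["COHORT_COLUMNS", "write_cohort_table", "read_cohort_table"]

_QUAL_COLUMNS = (
    "margins",
    *BOOL_FLAGS,
    "enhancement_art",
    "enhancement_port",
    "enhancement_pattern",
)

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "grade",
    "size_mm",
    *_QUAL_COLUMNS,
    *MeasurementSet.FIELDS,
    *RatioPanel.FIELDS,
    *TexturePanel.FIELDS,
    "n_voxels",
    "n_bins",
    "degenerate_flag",
    "extraction_ok",
    "error",
)


def record_to_row(rec: CohortRecord) -> dict:
    row: dict = {
        "patient_id": rec.patient_id,
        "grade": rec.grade,
        "size_mm": float(rec.size_mm),
        "extraction_ok": bool(rec.extraction_ok),
        "error": rec.error,
    }
    for col in _QUAL_COLUMNS:
        row[col] = getattr(rec.qualitative, col)
    for field in MeasurementSet.FIELDS:
        row[field] = getattr(rec.measurements, field) if rec.measurements else np.nan
    for field in RatioPanel.FIELDS:
        row[field] = getattr(rec.ratios, field) if rec.ratios else np.nan
    if rec.texture is not None:
        for field in TexturePanel.FIELDS:
            row[field] = getattr(rec.texture, field)
        row["n_voxels"] = rec.texture.n_voxels
        row["n_bins"] = rec.texture.n_bins
        row["degenerate_flag"] = rec.texture.degenerate_flag
    else:
        for field in TexturePanel.FIELDS:
            row[field] = np.nan
        row["n_voxels"] = -1
        row["n_bins"] = -1
        row["degenerate_flag"] = False
    return row


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("cohort is empty; refusing to write an empty table")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    return pd.DataFrame([record_to_row(r) for r in records], columns=list(COHORT_COLUMNS))


def write_cohort_table(records: list[CohortRecord], path: str | Path) -> None:
    """Write one CSV row per patient; round-trips via :func:`read_cohort_table`."""
    frame = records_to_frame(records)
    # repr-precision floats so the round trip is exact
    frame.to_csv(path, index=False, float_format="%.17g")


def _row_to_record(row: pd.Series) -> CohortRecord:
    qual = QualitativeRecord(**{c: _coerce_bool(row[c]) if c in BOOL_FLAGS else row[c] for c in _QUAL_COLUMNS})
    measurements = None
    if np.isfinite(row[list(MeasurementSet.FIELDS)].astype(float)).all():
        measurements = MeasurementSet(**{f: float(row[f]) for f in MeasurementSet.FIELDS})
    ratios = None
    if np.isfinite(row[list(RatioPanel.FIELDS)].astype(float)).all():
        ratios = RatioPanel(**{f: float(row[f]) for f in RatioPanel.FIELDS})
    texture = None
    if int(row["n_voxels"]) >= 0:
        texture = TexturePanel(
            **{f: float(row[f]) for f in TexturePanel.FIELDS},
            n_voxels=int(row["n_voxels"]),
            n_bins=int(row["n_bins"]),
            degenerate_flag=_coerce_bool(row["degenerate_flag"]),
        )
    return CohortRecord(
        patient_id=str(row["patient_id"]),
        grade=str(row["grade"]),
        size_mm=float(row["size_mm"]),
        qualitative=qual,
        measurements=measurements,
        ratios=ratios,
        texture=texture,
        extraction_ok=_coerce_bool(row["extraction_ok"]),
        error="" if pd.isna(row["error"]) else str(row["error"]),
    )


def _coerce_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1")


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    frame = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table {path} is missing columns: {sorted(missing)}")
    return [_row_to_record(row) for _, row in frame.iterrows()]
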