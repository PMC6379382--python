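"""Grade-group statistical layer.

Student's t for lesion sizes, Pearson chi-square for qualitative features,
pairwise two-sided Mann-Whitney U for ratio and texture features across
G1/G2/G3, and empirical ROC with cutoff sensitivity/specificity for every
feature significant in any pairwise comparison (positive class: G3 versus
G1+G2). Alpha is 0.05, two-sided, no multiplicity correction.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import (
    BOOL_FLAGS,
    ENHANCEMENT_LEVELS,
    GRADES,
    MARGIN_LEVELS,
    PATTERN_LEVELS,
    CohortRecord,
)
from .roi_quant import RatioPanel
from .texture3d import TexturePanel

__all__ = [
    "GroupComparison",
    "ROCResult",
    "GradeReport",
    "chi_square_test",
    "mann_whitney_test",
    "t_test_sizes",
    "roc_analysis",
    "grade_report",
    "percent_round_half_up",
    "DEFAULT_DIRECTIONS",
]

ALPHA = 0.05

#: Sample-size threshold below which the U test uses exact enumeration
#: (only when there are no ties).
EXACT_U_MAX_N = 16

GRADE_PAIRS = (("G1", "G2"), ("G2", "G3"), ("G1", "G3"))

QUANT_FEATURES: tuple[str, ...] = RatioPanel.FIELDS + TexturePanel.FIELDS

#: ROC direction per feature: enhancement ratios drop with grade, texture
#: heterogeneity features rise with grade.
DEFAULT_DIRECTIONS: dict[str, str] = {
    **{f: "lower_is_positive" for f in RatioPanel.FIELDS},
    "mean_value": "lower_is_positive",
    "variance": "higher_is_positive",
    "skewness": "higher_is_positive",
    "kurtosis": "higher_is_positive",
    "entropy": "higher_is_positive",
}


def percent_round_half_up(numerator: float, denominator: float) -> int:
    """Integer percentage with ties rounded up (97 for 30/31, 53 for 9/17)."""
    if denominator == 0:
        raise ZeroDivisionError("cannot take a percentage of an empty group")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    feature: str
    pair: tuple[str, str]
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclasses.dataclass
class ROCResult:
    feature: str
    direction: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def chi_square_test(contingency: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table: (chi2, df, p).

    Expected counts come from the margins; no continuity correction unless
    ``yates`` is set (2x2 only).
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("contingency counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero row or column")
    if yates and table.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U of sample a, p).

    Exact enumeration when ``n_a + n_b <= EXACT_U_MAX_N`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_U_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def t_test_sizes(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t for lesion sizes: (t, p)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 sizes")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher_is_positive",
    cutoff: float | None = None,
) -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC by trapezoid.

    Predicts positive when ``score >= t`` (ties at the threshold count as
    positive); for ``lower_is_positive`` the scores are negated internally
    but the reported thresholds/cutoff stay on the original scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC analysis")
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "higher_is_positive" else -1.0
    v = sign * s

    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    thr = np.unique(v)[::-1]
    tpr = np.empty(thr.size + 2)
    fpr = np.empty(thr.size + 2)
    tpr[0] = fpr[0] = 0.0
    for i, t in enumerate(thr, start=1):
        pred = v >= t
        tpr[i] = (pred & y).sum() / n_pos
        fpr[i] = (pred & ~y).sum() / n_neg
    tpr[-1] = fpr[-1] = 1.0
    auc = float(np.trapezoid(tpr, fpr))

    result = ROCResult(
        feature="", direction=direction, fpr=fpr, tpr=tpr,
        thresholds=sign * np.concatenate(([np.inf], thr, [-np.inf])),
        auc=auc,
    )
    if cutoff is not None:
        pred = v >= sign * cutoff
        result.cutoff = float(cutoff)
        result.sensitivity = float((pred & y).sum() / n_pos)
        result.specificity = float((~pred & ~y).sum() / n_neg)
    return result


# --------------------------------------------------------------------------
# Cohort-level report
# --------------------------------------------------------------------------

_QUAL_TABLES: dict[str, tuple[str, tuple[str, ...]]] = {
    "margins": ("margins", MARGIN_LEVELS),
    **{flag: (flag, ("absent", "present")) for flag in BOOL_FLAGS},
    "enhancement_art": ("enhancement_art", ENHANCEMENT_LEVELS),
    "enhancement_port": ("enhancement_port", ENHANCEMENT_LEVELS),
    "enhancement_pattern": ("enhancement_pattern", PATTERN_LEVELS),
}


@dataclasses.dataclass
class GradeReport:
    """Bundle of the four result-table analogs plus ROC results."""

    sizes: pd.DataFrame
    qualitative: dict[str, pd.DataFrame]
    qualitative_p: dict[str, float]
    quantitative_summary: pd.DataFrame
    pairwise: pd.DataFrame
    roc: dict[str, ROCResult]
    warnings: list[str]

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sizes.to_csv(out / "table_sizes.csv", index=False)
        qual = pd.concat(self.qualitative, names=["feature"]).reset_index(level=0)
        qual["chi2_p"] = qual["feature"].map(self.qualitative_p)
        qual.to_csv(out / "table1_qualitative.csv", index=True)
        self.quantitative_summary.to_csv(out / "table2_3_quantitative.csv", index=False)
        self.pairwise.to_csv(out / "table4_pairwise.csv", index=False)
        roc_rows = [
            dict(
                feature=f, direction=r.direction, auc=r.auc, cutoff=r.cutoff,
                sensitivity=r.sensitivity, specificity=r.specificity,
            )
            for f, r in self.roc.items()
        ]
        pd.DataFrame(
            roc_rows,
            columns=["feature", "direction", "auc", "cutoff", "sensitivity", "specificity"],
        ).to_csv(out / "roc.csv", index=False)
        summary = {
            "alpha": ALPHA,
            "warnings": self.warnings,
            "qualitative_p": self.qualitative_p,
            "roc_auc": {f: r.auc for f, r in self.roc.items()},
        }
        import json

        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def _qual_value(rec: CohortRecord, feature: str) -> str:
    v = getattr(rec.qualitative, feature)
    if isinstance(v, bool):
        return "present" if v else "absent"
    return v


def _qual_table(records: list[CohortRecord], feature: str, levels: tuple[str, ...], grades: list[str]) -> pd.DataFrame:
    rows = []
    for g in grades:
        group = [r for r in records if r.grade == g]
        counts = {lv: sum(1 for r in group if _qual_value(r, feature) == lv) for lv in levels}
        row = {"grade": g, "n": len(group)}
        for lv in levels:
            row[f"{lv}_n"] = counts[lv]
            row[f"{lv}_pct"] = percent_round_half_up(counts[lv], len(group))
        rows.append(row)
    total = {"grade": "all", "n": len(records)}
    for lv in levels:
        n_lv = sum(row[f"{lv}_n"] for row in rows)
        total[f"{lv}_n"] = n_lv
        total[f"{lv}_pct"] = percent_round_half_up(n_lv, len(records))
    return pd.DataFrame(rows + [total])


def _feature_values(records: list[CohortRecord], feature: str) -> dict[str, np.ndarray]:
    out = {}
    for g in GRADES:
        vals = []
        for r in records:
            if r.grade != g:
                continue
            panel = r.ratios if feature in RatioPanel.FIELDS else r.texture
            if panel is not None:
                vals.append(getattr(panel, feature))
        out[g] = np.asarray(vals, dtype=float)
    return out


def grade_report(
    cohort: list[CohortRecord],
    directions: dict[str, str] | None = None,
    cutoffs: dict[str, float] | None = None,
    alpha: float = ALPHA,
) -> GradeReport:
    """Full grade-group comparison: the analogs of result tables 1-4 plus ROC."""
    grades = sorted({r.grade for r in cohort})
    if len(grades) < 2:
        raise ValueError(f"need at least two grades for a comparison, got {grades}")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    cutoffs = cutoffs or {}
    warnings: list[str] = []

    # sizes: pairwise Student's t
    size_rows = []
    for ga, gb in GRADE_PAIRS:
        if ga not in grades or gb not in grades:
            continue
        a = [r.size_mm for r in cohort if r.grade == ga]
        b = [r.size_mm for r in cohort if r.grade == gb]
        t, p = t_test_sizes(a, b)
        size_rows.append(
            dict(pair=f"{ga}v{gb}", mean_a=np.mean(a), mean_b=np.mean(b), t=t, p=p)
        )
    sizes = pd.DataFrame(size_rows, columns=["pair", "mean_a", "mean_b", "t", "p"])

    # qualitative tables + chi-square
    qualitative: dict[str, pd.DataFrame] = {}
    qualitative_p: dict[str, float] = {}
    for feature, (_, levels) in _QUAL_TABLES.items():
        table = _qual_table(cohort, feature, levels, grades)
        qualitative[feature] = table
        counts = table.loc[table["grade"] != "all", [f"{lv}_n" for lv in levels]].to_numpy()
        nonzero_cols = counts.sum(axis=0) > 0
        try:
            _, _, p = chi_square_test(counts[:, nonzero_cols])
        except ValueError as exc:
            warnings.append(f"chi-square skipped for {feature}: {exc}")
            p = float("nan")
        qualitative_p[feature] = p

    # quantitative per-grade summaries + pairwise Mann-Whitney
    summary_rows = []
    pair_rows = []
    has_panels = any(r.ratios is not None or r.texture is not None for r in cohort)
    missing = [
        f for f in QUANT_FEATURES if all(v.size == 0 for v in _feature_values(cohort, f).values())
    ]
    if missing and has_panels:
        raise ValueError(f"missing feature columns in cohort: {missing}")
    if not has_panels:
        warnings.append("no quantitative panels present; qualitative-only report")
    for feature in QUANT_FEATURES if has_panels else ():
        by_grade = _feature_values(cohort, feature)
        for g in grades:
            v = by_grade[g]
            if v.size == 0:
                continue
            summary_rows.append(
                dict(
                    feature=feature, grade=g, n=v.size, minimum=v.min(), maximum=v.max(),
                    mean=v.mean(), median=float(np.median(v)),
                )
            )
        for ga, gb in GRADE_PAIRS:
            if ga not in grades or gb not in grades:
                continue
            va, vb = by_grade[ga], by_grade[gb]
            if va.size == 0 or vb.size == 0:
                continue
            u, p = mann_whitney_test(va, vb)
            pair_rows.append(
                dict(feature=feature, pair=f"{ga}v{gb}", U=u, p=p, n_a=va.size, n_b=vb.size)
            )
    quantitative_summary = pd.DataFrame(
        summary_rows,
        columns=["feature", "grade", "n", "minimum", "maximum", "mean", "median"],
    )
    pairwise = pd.DataFrame(pair_rows, columns=["feature", "pair", "U", "p", "n_a", "n_b"])

    # ROC (positive class: G3) for features significant in any pairwise test
    roc: dict[str, ROCResult] = {}
    if "G3" in grades:
        sig = sorted(
            set(pairwise.loc[pairwise["p"] < alpha, "feature"]), key=list(QUANT_FEATURES).index
        )
        if not sig:
            warnings.append("no feature significant in any pairwise comparison; ROC skipped")
        for feature in sig:
            by_grade = _feature_values(cohort, feature)
            scores = np.concatenate([by_grade[g] for g in grades])
            labels = np.concatenate(
                [np.full(by_grade[g].size, g == "G3", dtype=bool) for g in grades]
            )
            res = roc_analysis(
                scores, labels, directions.get(feature, "higher_is_positive"),
                cutoff=cutoffs.get(feature),
            )
            res.feature = feature
            roc[feature] = res
    else:
        warnings.append("no G3 group present; ROC skipped")

    return GradeReport(
        sizes=sizes,
        qualitative=qualitative,
        qualitative_p=qualitative_p,
        quantitative_summary=quantitative_summary,
        pairwise=pairwise,
        roc=roc,
        warnings=warnings,
    )
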