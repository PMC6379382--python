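from __future__ import annotations

import math

import numpy as np
import pytest

from pannen.records import CohortRecord, QualitativeRecord
from pannen.roi_quant import RatioPanel
from pannen.stats_grade import (
    QUANT_FEATURES,
    chi_square_test,
    grade_report,
    mann_whitney_test,
    percent_round_half_up,
    roc_analysis,
    t_test_sizes,
)
from pannen.texture3d import TexturePanel

from oracles import auc_pair_counting, mannwhitney_enumeration


class TestChiSquare:
    def test_proportional_rows_independent(self):
        chi2, df, p = chi_square_test([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_hand_computation(self):
        # E = 5 everywhere; chi2 = 4 * (10-5)^2/5 ... = 20
        chi2, df, p = chi_square_test([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_column_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            chi_square_test([[10, 0], [5, 0]])

    def test_1d_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[1, 2]])

    def test_yates_only_2x2(self):
        with pytest.raises(ValueError):
            chi_square_test([[1, 2, 3], [4, 5, 6]], yates=True)

    def test_three_by_two_df(self):
        _, df, _ = chi_square_test([[30, 1], [36, 16], [8, 9]])
        assert df == 2


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_test(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p >= 0.99

    @pytest.mark.parametrize("na,nb", [(na, nb) for na in range(1, 5) for nb in range(1, 5)])
    def test_enumeration_oracle_all_small_sizes(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na], pooled[na:]
            u_expect, p_expect = mannwhitney_enumeration(a, b)
            u, p = mann_whitney_test(a, b)
            assert u == pytest.approx(u_expect)
            assert p == pytest.approx(p_expect, rel=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])

    def test_type_one_error_rate_null(self):
        # smaller replicate count here; the full 10k-rep check is in acceptance
        rng = np.random.default_rng(77)
        reps = 2000
        rejects = 0
        for _ in range(reps):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            _, p = mann_whitney_test(a, b)
            rejects += p < 0.05
        assert rejects / reps == pytest.approx(0.05, abs=0.02)


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_sizes([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_worked_example(self):
        # pooled t = -sqrt(3) on df=6; two-sided p = 1 - sqrt(3)/2 exactly
        t, p = t_test_sizes([1, 2, 3, 4], [2, 4, 6, 8])
        assert t == pytest.approx(-math.sqrt(3), rel=1e-12)
        assert p == pytest.approx(1 - math.sqrt(3) / 2, rel=1e-10)

    def test_zero_variance_equal_means(self):
        assert t_test_sizes([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        t, p = t_test_sizes([5.0, 5.0], [7.0, 7.0])
        assert p == 0.0 and t == -np.inf

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            t_test_sizes([1.0], [2.0, 3.0])

    def test_published_size_regime_mostly_nonsignificant(self):
        # grade-size comparison at the published group sizes: mostly p > 0.05
        rng = np.random.default_rng(13)
        nonsig = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(44, 25, 31)
            b = rng.normal(52.35, 25, 17)
            _, p = t_test_sizes(a, b)
            nonsig += p > 0.05
        assert nonsig / reps > 0.5


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert r.auc == pytest.approx(1.0)

    def test_constant_scores_chance(self):
        r = roc_analysis([5.0] * 6, [True, False, True, False, False, True])
        assert r.auc == pytest.approx(0.5)

    def test_tie_pair_counting_example(self):
        # positives {2,3}, negatives {1,2}: (1 + 0.5 + 1 + 1)/4
        r = roc_analysis([2, 3, 1, 2], [True, True, False, False])
        assert r.auc == pytest.approx(0.875)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 7.0], size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc_analysis(scores, labels)
            assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
            assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
            assert np.all(np.diff(r.fpr) >= -1e-12)
            assert np.all(np.diff(r.tpr) >= -1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            pytest.skip("single class draw")
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_auc_u_duality_tie_free(self):
        rng = np.random.default_rng(8)
        scores = rng.permutation(np.arange(30.0))
        labels = np.array([i % 3 == 0 for i in range(30)])
        u, _ = mann_whitney_test(scores[labels], scores[~labels])
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_lower_is_positive_flips(self):
        scores = [1, 2, 3, 10, 11]
        labels = [True, True, True, False, False]
        assert roc_analysis(scores, labels, "lower_is_positive").auc == pytest.approx(1.0)
        assert roc_analysis(scores, labels, "higher_is_positive").auc == pytest.approx(0.0)

    def test_cutoff_sensitivity_specificity(self):
        scores = [0.1, 0.2, 0.9, 1.5, 2.0]
        labels = [False, False, True, True, True]
        r = roc_analysis(scores, labels, cutoff=0.9)
        assert r.sensitivity == pytest.approx(1.0)  # ties at the cutoff are positive
        assert r.specificity == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            roc_analysis([1.0, 2.0], [True, True])


class TestPercentages:
    @pytest.mark.parametrize(
        "num,den,expected", [(74, 100, 74), (30, 31, 97), (9, 17, 53), (16, 52, 31), (1, 31, 3)]
    )
    def test_published_margin_percentages(self, num, den, expected):
        assert percent_round_half_up(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent_round_half_up(1, 0)


def _cohort(n_per_grade=(8, 8, 8), seed=0, margin_counts=None):
    """Synthetic record list with grade-shifted kurtosis and margin flags."""
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for g, n, kurt_mu in zip(("G1", "G2", "G3"), n_per_grade, (0.0, 0.5, 2.5)):
        irregular = 0
        if margin_counts:
            irregular = margin_counts[g]
        for j in range(n):
            margins = "irregular" if j < irregular else "sharp"
            ratios = RatioPanel(*(rng.uniform(0.5, 1.5, 7)))
            texture = TexturePanel(
                mean_value=float(rng.normal(100, 10)), variance=float(rng.uniform(20, 80)),
                skewness=float(rng.normal(0, 0.2)), kurtosis=float(rng.normal(kurt_mu, 0.3)),
                entropy=float(rng.uniform(1, 5)), n_voxels=5000, n_bins=128, degenerate_flag=False,
            )
            records.append(
                CohortRecord(
                    patient_id=f"P{idx:03d}", grade=g, size_mm=float(rng.normal(45, 10)),
                    qualitative=QualitativeRecord(margins=margins),
                    ratios=ratios, texture=texture,
                )
            )
            idx += 1
    return records


class TestGradeReport:
    def test_pairwise_bookkeeping(self):
        report = grade_report(_cohort())
        # 7 ratios + 5 texture features, each with 3 grade pairs
        assert len(report.pairwise) == len(QUANT_FEATURES) * 3 == 36
        assert set(report.pairwise["pair"]) == {"G1vG2", "G2vG3", "G1vG3"}

    def test_published_margin_counts_significant(self):
        records = _cohort(
            n_per_grade=(31, 52, 17), margin_counts={"G1": 1, "G2": 16, "G3": 9}
        )
        report = grade_report(records)
        assert report.qualitative_p["margins"] < 0.05
        table = report.qualitative[
            "margins"
        ].set_index("grade")
        assert table.loc["G1", "sharp_pct"] == 97
        assert table.loc["G3", "irregular_pct"] == 53
        assert table.loc["G2", "irregular_pct"] == 31
        assert table.loc["all", "sharp_pct"] == 74

    def test_percentages_sum_to_100_pm_1(self):
        report = grade_report(_cohort(seed=5))
        for feature, table in report.qualitative.items():
            pct_cols = [c for c in table.columns if c.endswith("_pct")]
            sums = table[pct_cols].sum(axis=1)
            assert ((sums - 100).abs() <= 1).all(), feature

    def test_roc_runs_for_significant_kurtosis(self):
        report = grade_report(_cohort(n_per_grade=(15, 15, 15), seed=2))
        assert "kurtosis" in report.roc
        assert report.roc["kurtosis"].auc > 0.8
        assert report.roc["kurtosis"].direction == "higher_is_positive"

    def test_single_grade_errors(self):
        records = [r for r in _cohort() if r.grade == "G1"]
        with pytest.raises(ValueError, match="two grades"):
            grade_report(records)

    def test_report_write(self, tmp_path):
        report = grade_report(_cohort())
        report.write(tmp_path / "report")
        for name in (
            "table_sizes.csv", "table1_qualitative.csv", "table2_3_quantitative.csv",
            "table4_pairwise.csv", "roc.csv", "summary.json",
        ):
            assert (tmp_path / "report" / name).exists()
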