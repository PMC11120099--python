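"""Diagnostic-accuracy machinery: metrics, AUC/DeLong, Youden, reports."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vapscore import (
    DEFAULT_RULES,
    ConfusionMatrix,
    ThresholdRule,
    ValidationError,
    auc_mann_whitney,
    confusion_from_predictions,
    delong_ci,
    delong_paired_pvalue,
    evaluate_panel,
    group_compare,
    predictive_metrics,
    roc_analysis,
    roc_points,
    wilson_ci,
    youden_threshold,
)
from vapscore.evaluation import delong_variance


def brute_force_auc(scores, labels) -> float:
    """Pair-counting oracle: concordant pairs plus half the ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestPredictiveMetrics:
    def test_direct_formula_example(self):
        m = predictive_metrics(ConfusionMatrix(tp=8, fn=2, tn=9, fp=3))
        assert m.sn == pytest.approx(0.80)
        assert m.sp == pytest.approx(0.75)
        assert m.ppv == pytest.approx(0.727, abs=5e-4)
        assert m.npv == pytest.approx(0.818, abs=5e-4)
        for est, ci in [(m.sn, m.sn_ci), (m.sp, m.sp_ci), (m.ppv, m.ppv_ci), (m.npv, m.npv_ci)]:
            assert ci[0] <= est <= ci[1]

    def test_perfect_classifier(self):
        m = predictive_metrics(ConfusionMatrix(tp=10, fn=0, tn=12, fp=0))
        assert (m.sn, m.sp, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_wilson_closed_form(self):
        """38 of 49: Wilson 95% CI ≈ (0.64, 0.87), recomputed from the
        closed form with z = 1.959964."""
        lo, hi = wilson_ci(38, 49)
        z = stats.norm.ppf(0.975)
        p, n = 38 / 49, 49
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert lo == pytest.approx(centre - half, abs=1e-9)
        assert hi == pytest.approx(centre + half, abs=1e-9)
        assert (round(lo, 2), round(hi, 2)) == (0.64, 0.87)

    def test_zero_denominator_returns_none_for_that_metric(self):
        m = predictive_metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=3))
        assert m.sn is None and m.sn_ci is None
        assert m.sp == pytest.approx(5 / 8)

    def test_confusion_from_predictions_skips_undetermined(self):
        cm = confusion_from_predictions(
            ["positive", "negative", "undetermined", "positive"],
            [True, True, True, False],
        )
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 0)


class TestAuc:
    def test_small_example(self):
        assert auc_mann_whitney([3, 5, 1, 4], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_mann_whitney([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc_mann_whitney([2, 2, 2, 2], [1, 1, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        """200 random small instances with heavy ties: rank formula equals
        the pair-counting oracle exactly."""
        for _ in range(200):
            n = rng.integers(4, 25)
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or (~labels).all():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_equals_trapezoidal_roc_area(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.normal(size=n).round(1)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or (~labels).all():
                continue
            pts = roc_points(scores, labels).sort_values("sp")
            area = np.trapezoid(pts["sn"].to_numpy(), pts["sp"].to_numpy())
            assert auc_mann_whitney(scores, labels) == pytest.approx(area)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60).astype(bool)
        a1 = auc_mann_whitney(scores, labels)
        a2 = auc_mann_whitney(np.exp(2 * scores) + 3, labels)
        assert a1 == pytest.approx(a2)

    def test_label_flip_symmetry(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        assert auc_mann_whitney(scores, ~labels) == pytest.approx(
            1 - auc_mann_whitney(scores, labels)
        )

    def test_nan_scores_excluded(self):
        assert auc_mann_whitney([3, 5, np.nan, 1, 4], [1, 1, 1, 0, 0]) == pytest.approx(0.75)


class TestDeLong:
    def test_hand_computed_example(self):
        """Positives {3,5}, negatives {1,4}: placement values V10={0.5,1},
        V01={1,0.5}, Var = 0.125/2 + 0.125/2 = 0.125."""
        auc, var = delong_variance([3, 5, 1, 4], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)
        assert var == pytest.approx(0.125)
        auc, lo, hi = delong_ci([3, 5, 1, 4], [1, 1, 0, 0])
        assert lo == pytest.approx(0.75 - 1.959964 * math.sqrt(0.125), abs=1e-4)
        assert hi == 1.0  # clipped

    def test_variance_nonnegative_and_zero_iff_constant_placements(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or (~labels).all():
                continue
            _, var = delong_variance(scores, labels)
            assert var >= 0

    def test_perfect_separation_degenerates(self):
        auc, lo, hi = delong_ci([10, 11, 1, 2], [1, 1, 0, 0])
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_ci_matches_bootstrap_percentile(self):
        """n=200 synthetic scores: DeLong CI within 0.03 of a 2000-rep
        bootstrap percentile CI on each bound."""
        rng = np.random.default_rng(7)
        labels = rng.random(200) < 0.45
        scores = rng.normal(loc=np.where(labels, 1.0, 0.0), scale=1.0)
        auc, lo, hi = delong_ci(scores, labels)
        boot = []
        idx = np.arange(200)
        for _ in range(2000):
            take = rng.choice(idx, size=200, replace=True)
            y = labels[take]
            if y.all() or (~y).all():
                continue
            boot.append(auc_mann_whitney(scores[take], y))
        b_lo, b_hi = np.percentile(boot, [2.5, 97.5])
        assert lo == pytest.approx(b_lo, abs=0.03)
        assert hi == pytest.approx(b_hi, abs=0.03)

    def test_identical_scores_give_p_one(self):
        s = [3, 5, 1, 4, 2, 6]
        y = [1, 1, 0, 0, 1, 0]
        assert delong_paired_pvalue(s, s, y) == 1.0

    def test_detects_cpis_lus_improvement_across_replicates(self):
        """Under the calibrated generator the ultrasound composite beats
        CPIS by a wide margin, so the paired DeLong test at n = 300 should
        reject AUC equality in at least 90 of 100 seeded replicates."""
        from vapscore import generate_frame, score_frame

        rejections = 0
        for seed in range(100):
            scored = score_frame(generate_frame(n=300, seed=10_000 + seed))
            y = scored["vap_confirmed"].to_numpy(dtype=bool)
            cpis = scored["cpis"].to_numpy(dtype=float)
            cpis_lus = scored["cpis_lus"].to_numpy(dtype=float)
            rejections += delong_paired_pvalue(cpis_lus, cpis, y) < 0.05
        assert rejections >= 90

    def test_paired_z_matches_permutation_oracle(self):
        """Small paired instance: the DeLong z statistic agrees with a
        sign-flip permutation test of the paired AUC difference
        (10⁵ shuffles) within 0.2."""
        rng = np.random.default_rng(3)
        y = np.array([1] * 5 + [0] * 5, dtype=bool)
        a = np.where(y, rng.normal(1.2, 1, 10), rng.normal(0, 1, 10))
        b = a * 0.5 + rng.normal(0, 1, 10)
        p = delong_paired_pvalue(a, b, y)
        z_delong = abs(stats.norm.ppf(p / 2))

        diff_obs = auc_mann_whitney(a, y) - auc_mann_whitney(b, y)
        n_shuffles = 10**5
        flips = rng.random((n_shuffles, 10)) < 0.5
        a_mat = np.where(flips, b, a)
        b_mat = np.where(flips, a, b)

        def auc_rows(mat):
            ranks = stats.rankdata(mat, axis=1)
            n1 = y.sum()
            u = ranks[:, y].sum(axis=1) - n1 * (n1 + 1) / 2
            return u / (n1 * (~y).sum())

        diffs = auc_rows(a_mat) - auc_rows(b_mat)
        z_perm = abs(diff_obs) / diffs.std(ddof=1)
        assert z_delong == pytest.approx(z_perm, abs=0.2)


class TestYouden:
    def test_tie_broken_to_lowest_threshold(self):
        t, j, sn, sp = youden_threshold([3, 5, 1, 4], [1, 1, 0, 0])
        assert t == 3 and j == pytest.approx(0.5)
        assert j == pytest.approx(sn + sp - 1)

    def test_perfect_separation(self):
        t, j, sn, sp = youden_threshold([5, 6, 1, 2], [1, 1, 0, 0])
        assert t == 5 and j == pytest.approx(1.0)

    def test_beats_every_other_cutoff_exhaustively(self, rng):
        """Integer scores 0..21: the returned J equals the maximum over
        every candidate cutoff (brute-force oracle)."""
        for _ in range(50):
            n = int(rng.integers(10, 80))
            scores = rng.integers(0, 22, size=n).astype(float)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or (~labels).all():
                continue
            t, j, sn, sp = youden_threshold(scores, labels)
            assert j == pytest.approx(sn + sp - 1)
            y = labels
            for cand in np.unique(scores):
                pred = scores >= cand
                j_cand = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
                assert j >= j_cand - 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValidationError):
            youden_threshold([1, 2], [1, 1])


class TestRocAnalysis:
    def test_monotone_operating_points(self, rng):
        scores = rng.integers(0, 10, size=60).astype(float)
        labels = rng.integers(0, 2, size=60).astype(bool)
        res = roc_analysis(scores, labels)
        assert (np.diff(res.sn) <= 1e-12).all()      # sn non-increasing in t
        assert (np.diff(res.sp) >= -1e-12).all()     # sp non-decreasing in t
        assert res.youden_j == pytest.approx(
            max(s + p - 1 for s, p in zip(res.sn, res.sp))
        )


class TestEvaluatePanel:
    def test_report_shape_and_consistency(self, default_cohort_500):
        report = evaluate_panel(default_cohort_500, DEFAULT_RULES)
        assert len(report.table) == 5
        metric_cols = [c for c in report.table.columns
                       if c.split("_")[0] in ("auc", "sn", "sp", "ppv", "npv")]
        vals = report.table[metric_cols].to_numpy(dtype=float)
        assert ((vals >= 0) & (vals <= 1)).all()
        # ultrasound scores are evaluated on the examined subcohort only
        lus_row = report.table.set_index("score").loc["lus"]
        n_lus = int(default_cohort_500["lus_performed"].sum())
        assert lus_row["n_included"] == n_lus
        assert lus_row["n_excluded"] == len(default_cohort_500) - n_lus

    def test_row_equals_direct_metric_computation(self, default_cohort_500):
        report = evaluate_panel(default_cohort_500, [ThresholdRule("cpis", 6, "gt")])
        row = report.table.iloc[0]
        s = default_cohort_500["cpis"].to_numpy(dtype=float)
        y = default_cohort_500["vap_confirmed"].to_numpy(dtype=bool)
        cm = confusion_from_predictions(
            ["positive" if v > 6 else "negative" for v in s], y
        )
        m = predictive_metrics(cm)
        assert row["sn"] == pytest.approx(m.sn)
        assert row["sp"] == pytest.approx(m.sp)
        assert row["auc"] == pytest.approx(auc_mann_whitney(s, y))

    def test_full_vs_lus_subset_auc_differ(self, default_cohort_500):
        """Evaluating CPIS on everyone vs on the ultrasound subcohort gives
        different AUCs — the whole-cohort/subcohort distinction matters."""
        full = evaluate_panel(default_cohort_500, [ThresholdRule("cpis", 6, "gt")])
        subset = evaluate_panel(
            default_cohort_500[default_cohort_500["lus_performed"] == 1],
            [ThresholdRule("cpis", 6, "gt")],
        )
        assert full.table.loc[0, "auc"] != pytest.approx(subset.table.loc[0, "auc"], abs=1e-6)

    def test_all_na_score_column_raises(self, default_cohort_500):
        df = default_cohort_500.copy()
        df["cpis_plus"] = pd.NA
        with pytest.raises(ValidationError):
            evaluate_panel(df, [ThresholdRule("cpis_plus", 12)])

    def test_serialization_roundtrip(self, default_cohort_500, tmp_path):
        report = evaluate_panel(default_cohort_500, DEFAULT_RULES)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = pd.read_csv(path)
        assert list(back["rule"]) == [r.label for r in DEFAULT_RULES]
        from io import StringIO

        assert "auc" in pd.read_json(StringIO(report.to_json())).columns


class TestGroupCompare:
    def test_secretions_association(self):
        """Published 3×2 secretion counts: chi-square p consistent with the
        printed 0.001."""
        df = pd.DataFrame({
            "vap_confirmed": [1] * 51 + [0] * 57,
            "secretions": (["absent_minimal"] * 12 + ["non_purulent"] * 24 + ["purulent"] * 15
                           + ["absent_minimal"] * 32 + ["non_purulent"] * 23 + ["purulent"] * 2),
        })
        p = group_compare(df, "secretions", "categorical")
        assert p < 0.0015

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({
            "vap_confirmed": [1] * 10 + [0] * 10,
            "x": list(range(10)) * 2,
        })
        assert group_compare(df, "x", "continuous_skewed") == pytest.approx(1.0)
        assert group_compare(df, "x", "continuous_normal") == pytest.approx(1.0)

    def test_rank_sum_close_to_exact_enumeration_at_small_n(self):
        """continuous_skewed uses the normal approximation with tie
        correction; at n ≤ 8 it stays close to the exact permutation
        distribution of the rank sum."""
        df = pd.DataFrame({
            "vap_confirmed": [1, 1, 1, 1, 0, 0, 0, 0],
            "x": [7.0, 5.0, 6.0, 9.0, 1.0, 2.0, 3.0, 8.0],
        })
        p_approx = group_compare(df, "x", "continuous_skewed")
        a = df.loc[df.vap_confirmed == 1, "x"].to_numpy()
        b = df.loc[df.vap_confirmed == 0, "x"].to_numpy()
        p_exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p_approx == pytest.approx(p_exact, abs=0.05)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"vap_confirmed": [1, 1], "x": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            group_compare(df, "x", "continuous_normal")
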