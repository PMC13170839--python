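"""Evaluation statistics: exhaustive-enumeration and hand-worked oracles."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from synthrad.evalstats import (
    ReaderStudyTable, auc, calibration_curve, confusion_metrics,
    decision_curve, delong_test, delong_variance, mann_whitney_auc, nri_idi,
    reader_study_summary,
)

TABLE3 = Path(__file__).parent / "data" / "table3_reader_study.csv"


class TestAUC:
    def test_perfect_separation(self):
        res = auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=100, seed=0)
        assert res.auc == 1.0

    def test_six_point_toy_equals_pairwise_concordance(self):
        """Scores 1..6, labels 001011: brute-force count over all nine
        positive-negative pairs."""
        scores = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        labels = np.array([0, 0, 1, 0, 1, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = conc / (pos.size * neg.size)
        assert mann_whitney_auc(scores, labels) == pytest.approx(expected)

    def test_chance_level_when_independent(self):
        r = np.random.default_rng(5)
        res = auc(r.uniform(size=200), r.integers(0, 2, 200), n_boot=200, seed=5)
        assert 0.4 <= res.auc <= 0.6

    def test_trapezoid_equals_mann_whitney(self):
        r = np.random.default_rng(8)
        scores = np.round(r.uniform(size=100), 2)  # force ties
        labels = r.integers(0, 2, 100)
        res = auc(scores, labels, n_boot=100, seed=8)
        assert res.trapezoid_auc() == pytest.approx(res.auc, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        r = np.random.default_rng(9)
        scores = r.uniform(size=80) + 0.5 * r.integers(0, 2, 80)
        labels = (scores > np.median(scores)).astype(int)
        res = auc(scores, labels, n_boot=500, seed=9)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.9], [1, 1], n_boot=10, seed=0)


class TestDeLong:
    def test_identical_predictions(self):
        r = np.random.default_rng(1)
        p = r.uniform(size=60)
        y = r.integers(0, 2, 60)
        z, pval = delong_test(p, p, y)
        assert z == 0.0 and pval == 1.0

    def test_antisymmetry(self):
        r = np.random.default_rng(2)
        y = r.integers(0, 2, 80)
        a = r.uniform(size=80) + 0.4 * y
        b = r.uniform(size=80) + 0.1 * y
        z_ab, _ = delong_test(a, b, y)
        z_ba, _ = delong_test(b, a, y)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)
        assert z_ab != 0.0

    def test_component_variance_matches_bootstrap(self):
        """Structural-components AUC variance within 20% of a
        2000-replicate bootstrap on a seeded n=100 sample."""
        r = np.random.default_rng(3)
        y = np.array([0] * 50 + [1] * 50)
        s = r.uniform(size=100) + 0.6 * y
        var = delong_variance(s, y)
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        reps = np.empty(2000)
        for b in range(2000):
            idx = np.concatenate([r.choice(pos, 50), r.choice(neg, 50)])
            reps[b] = mann_whitney_auc(s[idx], y[idx])
        assert var == pytest.approx(reps.var(ddof=1), rel=0.2)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])


class TestNRIIDI:
    def test_no_change_gives_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 1, 0, 1])
        res = nri_idi(p, p, y)
        assert res.nri == 0.0 and res.idi == 0.0

    def test_maximal_improvement_nri_two(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.5, 0.6, 0.5, 0.4])
        p_new = p_old + np.where(y == 1, 0.1, -0.1)
        assert nri_idi(p_old, p_new, y).nri == pytest.approx(2.0)

    def test_eight_case_hand_worked_example(self):
        """4 events .2/.4/.6/.8 -> .3/.3/.7/.9; 4 nonevents .2/.4/.6/.8 ->
        .1/.5/.5/.7.  By hand: events up 3/4 down 1/4; nonevents up 1/4
        down 3/4 -> NRI = 0.5 + 0.5 = 1.0.  IDI = mean event rise 0.05
        minus mean nonevent rise (-0.05) = 0.1."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        p_old = np.array([0.2, 0.4, 0.6, 0.8, 0.2, 0.4, 0.6, 0.8])
        p_new = np.array([0.3, 0.3, 0.7, 0.9, 0.1, 0.5, 0.5, 0.7])
        res = nri_idi(p_old, p_new, y)
        assert res.nri == pytest.approx(1.0)
        assert res.idi == pytest.approx(0.1)
        assert res.p_up_event == pytest.approx(0.75)
        assert res.p_down_nonevent == pytest.approx(0.75)

    def test_idi_equals_discrimination_slope_difference(self):
        r = np.random.default_rng(4)
        y = r.integers(0, 2, 100)
        p_old = np.clip(r.uniform(size=100) + 0.2 * y, 0, 1)
        p_new = np.clip(r.uniform(size=100) + 0.3 * y, 0, 1)
        slope_new = p_new[y == 1].mean() - p_new[y == 0].mean()
        slope_old = p_old[y == 1].mean() - p_old[y == 0].mean()
        res = nri_idi(p_old, p_new, y)
        assert res.idi == pytest.approx(slope_new - slope_old, abs=1e-12)

    def test_bounds_always_hold(self):
        r = np.random.default_rng(6)
        for _ in range(20):
            y = r.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            res = nri_idi(r.uniform(size=30), r.uniform(size=30), y)
            assert -2.0 <= res.nri <= 2.0
            assert -1.0 <= res.idi <= 1.0

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            nri_idi([0.5, 1.2], [0.5, 0.5], [0, 1])


class TestConfusion:
    def test_all_correct(self):
        res = confusion_metrics(["fibrous", "soft"], ["fibrous", "soft"])
        assert res["accuracy"]["value"] == 1.0
        assert res["sensitivity"]["value"] == 1.0
        assert res["specificity"]["value"] == 1.0

    def test_hand_counts(self):
        # TP=3 FN=1 TN=4 FP=2
        true = ["fibrous"] * 4 + ["soft"] * 6
        pred = (["fibrous"] * 3 + ["soft"]) + (["fibrous"] * 2 + ["soft"] * 4)
        res = confusion_metrics(pred, true)
        assert res["sensitivity"]["value"] == pytest.approx(0.75)
        assert res["specificity"]["value"] == pytest.approx(2 / 3)
        assert res["accuracy"]["value"] == pytest.approx(0.7)

    def test_consistency_with_raw_vectors(self):
        r = np.random.default_rng(11)
        true = np.where(r.uniform(size=50) > 0.4, "fibrous", "soft")
        pred = np.where(r.uniform(size=50) > 0.5, "fibrous", "soft")
        res = confusion_metrics(pred, true)
        c = res["counts"]
        assert res["accuracy"]["value"] == pytest.approx(
            (c["tp"] + c["tn"]) / 50)
        lo, hi = res["sensitivity"]["ci_low"], res["sensitivity"]["ci_high"]
        assert lo <= res["sensitivity"]["value"] <= hi


class TestReaderStudy:
    def test_published_table_pooled_metrics(self):
        table = ReaderStudyTable.from_csv(TABLE3, arm_size=25)
        summary = reader_study_summary(table)
        r1 = summary["per_reader"]["radiologist_1"]
        r2 = summary["per_reader"]["radiologist_2"]
        assert r1["specificity"] == pytest.approx(0.800)
        assert r2["sensitivity"] == pytest.approx(0.200)
        assert summary["mean_synthetic_detection"] == pytest.approx(0.193, abs=5e-4)

    def test_discrepancy_flags_for_printed_values(self):
        """The printed R1 sensitivity (0.173) and accuracy (0.487) do not
        match the table's own cell sums (14/75, 74/150) and are flagged."""
        table = ReaderStudyTable.from_csv(TABLE3, arm_size=25)
        summary = reader_study_summary(table, printed_values={
            "radiologist_1": {"sensitivity": 0.173, "accuracy": 0.487,
                              "specificity": 0.800},
            "radiologist_2": {"sensitivity": 0.200},
        })
        joined = " ".join(summary["discrepancies"])
        assert "radiologist_1 sensitivity" in joined
        assert "radiologist_1 accuracy" in joined
        assert "specificity" not in joined

    def test_inconsistent_arm_size_rejected(self):
        tab = pd.read_csv(TABLE3)
        tab.loc[0, "called_real"] = 99
        with pytest.raises(ValueError, match="arm size"):
            ReaderStudyTable(tab, arm_size=25)


class TestCalibration:
    def test_simulated_perfectly_calibrated_scores(self):
        r = np.random.default_rng(12)
        p = r.uniform(0.05, 0.95, 5000)
        y = (r.uniform(size=5000) < p).astype(int)
        res = calibration_curve(p, y, n_bins=10)
        assert 0.9 <= res["slope"] <= 1.1

    def test_constant_probability_bins(self):
        p = np.full(50, 0.3)
        y = (np.arange(50) < 15).astype(int)  # event rate 0.3
        res = calibration_curve(p, y, n_bins=5)
        assert np.allclose(res["bin_mean_p"], 0.3)
        assert np.mean(res["bin_event_rate"]) == pytest.approx(0.3)

    def test_anticalibrated_scores_negative_association(self):
        r = np.random.default_rng(13)
        p = r.uniform(0.05, 0.95, 2000)
        y = (r.uniform(size=2000) < p).astype(int)
        res = calibration_curve(1.0 - p, y, n_bins=10)
        corr = np.corrcoef(res["bin_mean_p"], res["bin_event_rate"])[0, 1]
        assert corr < 0


class TestDecisionCurve:
    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.array([1] * 3 + [0] * 7)  # prevalence 0.3
        p = np.linspace(0.1, 0.9, 10)
        dc = decision_curve(p, y, [0.3])
        assert dc["net_benefit_treat_all"].iloc[0] == pytest.approx(0.0)

    def test_perfect_model_net_benefit_is_prevalence(self):
        y = np.array([1] * 4 + [0] * 6)
        p = y.astype(float) * 0.98 + 0.01
        dc = decision_curve(p, y, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert np.allclose(dc["net_benefit_model"], 0.4)

    def test_ten_case_hand_tabulation_at_t03(self):
        """p >= 0.3 treats 5 cases: TP=3, FP=2 by hand ->
        NB = 3/10 - 2/10 * 3/7."""
        p = np.array([0.9, 0.8, 0.4, 0.2, 0.1, 0.35, 0.6, 0.05, 0.15, 0.25])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1])
        dc = decision_curve(p, y, [0.3])
        assert dc["net_benefit_model"].iloc[0] == pytest.approx(
            0.3 - 0.2 * 0.3 / 0.7)

    def test_treat_all_closed_form_everywhere(self):
        r = np.random.default_rng(14)
        y = r.integers(0, 2, 40)
        p = r.uniform(size=40)
        grid = np.linspace(0.05, 0.95, 19)
        dc = decision_curve(p, y, grid)
        prev = y.mean()
        expected = prev - (1 - prev) * grid / (1 - grid)
        assert np.allclose(dc["net_benefit_treat_all"], expected)

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            decision_curve([0.5], [1], [0.0])
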