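"""ROC/DeLong, agreement, survival and group-comparison statistics."""

import numpy as np
import pytest

from adcresponse.errors import DomainError
from adcresponse.stateval import (
    ConfusionTable,
    binary_marker_auc,
    confusion_metrics,
    delong_compare,
    empirical_roc,
    group_compare,
    icc_two_way_mixed_absolute,
    km_logrank,
    weighted_kappa,
)

from oracles import auc_pair_counting, linear_weighted_kappa, youden_exhaustive


class TestConfusion:
    def test_study_scale_examples(self):
        m = confusion_metrics(ConfusionTable(tp=10, fp=0, tn=26, fn=2))
        assert m["sensitivity"].percent == 83
        assert m["specificity"].percent == 100
        assert m["accuracy"].percent == 95
        m2 = confusion_metrics(ConfusionTable(tp=9, fp=3, tn=23, fn=3))
        assert m2["accuracy"].percent == 84

    def test_all_correct(self):
        m = confusion_metrics(ConfusionTable(tp=5, fp=0, tn=7, fn=0))
        assert all(v.percent == 100 for v in m.values())

    def test_percent_round_trips_to_fraction(self):
        m = confusion_metrics(ConfusionTable(tp=10, fp=5, tn=21, fn=2))
        ppv = m["ppv"]
        assert (ppv.numerator, ppv.denominator) == (10, 15)
        assert ppv.percent == 67  # 66.7 rounds half-up to 67

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionTable(tp=0, fp=0, tn=5, fn=0))
        assert m["ppv"].percent is None
        assert str(m["ppv"]) == "undefined"

    def test_single_point_auc(self):
        assert binary_marker_auc(ConfusionTable(10, 0, 26, 2)) == pytest.approx(
            0.9166667, abs=1e-6
        )
        assert binary_marker_auc(ConfusionTable(5, 0, 26, 7)) == pytest.approx(
            0.7083333, abs=1e-6
        )
        assert binary_marker_auc(ConfusionTable(12, 0, 26, 0)) == 1.0


class TestEmpiricalROC:
    def test_perfect_separation(self):
        roc = empirical_roc([1, 2, 3, 4], [False, False, True, True])
        assert roc.auc == 1.0
        assert roc.youden_cutoff == pytest.approx(2.5)
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0

    def test_tied_scores_half_weight(self):
        # pairs: (2,1)=1, (2,2)=0.5, (3,1)=1, (3,2)=1 -> 3.5/4
        scores, labels = [1, 2, 2, 3], [False, True, False, True]
        roc = empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(auc_pair_counting(scores, labels))
        assert roc.auc == pytest.approx(0.875)

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.uniform(size=2000) < 0.5
        roc = empirical_roc(scores, labels)
        assert abs(roc.auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = rng.uniform(size=n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_youden_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        scores[labels] += rng.uniform(0.2, 1.0)
        roc = empirical_roc(scores, labels)
        cut, sens, spec = youden_exhaustive(scores, labels)
        assert roc.youden_cutoff == pytest.approx(cut)
        assert roc.sens_at_cutoff == pytest.approx(sens)
        assert roc.spec_at_cutoff == pytest.approx(spec)

    def test_less_positive_direction(self):
        scores = np.array([10.0, 8.0, 3.0, 1.0])
        labels = np.array([False, False, True, True])
        roc = empirical_roc(scores, labels, direction="less-positive")
        assert roc.auc == 1.0
        assert roc.youden_cutoff == pytest.approx(5.5)

    def test_one_class_absent_rejected(self):
        with pytest.raises(DomainError):
            empirical_roc([1.0, 2.0], [True, True])


class TestDeLong:
    def test_identical_markers_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=50)
        y = np.concatenate([np.zeros(25, bool), np.ones(25, bool)])
        assert delong_compare(s, s, y) == 1.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        y = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        for _ in range(reps):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            if delong_compare(a, b, y) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_informative_marker(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([np.zeros(100, bool), np.ones(100, bool)])
        informative = y.astype(float) + 0.01 * rng.normal(size=200)
        noise = rng.normal(size=200)
        assert delong_compare(informative, noise, y) < 0.01


class TestAgreement:
    def test_perfect_agreement_icc_one(self, rng):
        r1 = rng.normal(1200, 200, size=30)
        icc = icc_two_way_mixed_absolute(np.column_stack([r1, r1]))
        assert icc.value == pytest.approx(1.0, abs=1e-12)

    def test_fixed_bias_lowers_absolute_agreement(self, rng):
        r1 = rng.normal(1200, 100, size=60)
        r2 = r1 + 250.0  # perfectly consistent, systematically offset
        icc_abs = icc_two_way_mixed_absolute(np.column_stack([r1, r2])).value
        assert icc_abs < 0.6

    def test_variance_component_construction(self):
        rng = np.random.default_rng(11)
        n = 500
        s_item, s_rater, s_err = 1.0, 0.15, 0.30
        items = rng.normal(0, s_item, size=n)
        raters = rng.normal(0, s_rater, size=2)
        x = items[:, None] + raters[None, :] + rng.normal(0, s_err, size=(n, 2))
        expected = s_item**2 / (s_item**2 + s_rater**2 + s_err**2)
        icc = icc_two_way_mixed_absolute(x)
        assert icc.value == pytest.approx(expected, abs=0.05)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        items = rng.normal(1000, 150, size=25)
        x = items[:, None] + np.array([0.0, 40.0]) + rng.normal(0, 60, size=(25, 2))
        ours = icc_two_way_mixed_absolute(x)
        df = pd.DataFrame(
            {
                "item": np.repeat(np.arange(25), 2),
                "rater": np.tile([0, 1], 25),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="item", raters="rater",
                                       ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert ours.value == pytest.approx(row["ICC"], abs=1e-6)
        assert ours.ci95[0] == pytest.approx(row[ci_col][0], abs=0.02)
        assert ours.ci95[1] == pytest.approx(row[ci_col][1], abs=0.02)

    def test_kappa_identical_is_one(self):
        cats = ["a", "b", "c", "a", "b", "c", "a"]
        assert weighted_kappa(cats, list(cats), categories=["a", "b", "c"]) == 1.0

    def test_kappa_independent_is_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.choice(["x", "y", "z"], size=5000)
        b = rng.choice(["x", "y", "z"], size=5000)
        assert abs(weighted_kappa(a, b, categories=["x", "y", "z"])) < 0.05

    def test_kappa_matches_hand_formula(self):
        rng = np.random.default_rng(2)
        cats = ["nonviable", "equivocal", "viable"]
        a = rng.choice(cats, size=200, p=[0.2, 0.3, 0.5]).tolist()
        b = [
            x if rng.uniform() < 0.7 else rng.choice(cats)
            for x in a
        ]
        ours = weighted_kappa(a, b, categories=cats)
        assert ours == pytest.approx(linear_weighted_kappa(a, b, cats), abs=1e-12)


class TestSurvival:
    def test_no_events_curve_stays_at_one(self):
        res = km_logrank([10, 20, 30], [False, False, False])
        g = res.groups["all"]
        assert all(v == 1.0 for v in g.milestone_rates.values() if v == v)
        assert np.isinf(g.median_months)

    def test_identical_groups_logrank_null(self):
        t = [5, 10, 15, 20, 25, 30]
        e = [True, True, False, True, False, True]
        res = km_logrank(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_km_matches_exponential_closed_form(self):
        rng = np.random.default_rng(5)
        lam = 0.03
        n = 2000
        t = rng.exponential(1 / lam, size=n)
        res = km_logrank(t, [True] * n, milestones=(12.0, 36.0, 60.0))
        g = res.groups["all"]
        for ms, rate in g.milestone_rates.items():
            expected = np.exp(-lam * ms)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(rate - expected) < 2 * se


class TestGroupCompare:
    def test_identical_groups_t_path(self, rng):
        v = rng.normal(10, 2, size=15)
        res = group_compare(np.concatenate([v, v]), [True] * 15 + [False] * 15)
        assert res.test == "Student t"
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_detected(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(3.5, 1, size=20)
        res = group_compare(np.concatenate([a, b]), [True] * 20 + [False] * 20)
        assert res.p_value < 1e-3

    def test_tiny_group_uses_mann_whitney(self, rng):
        v = np.concatenate([[1.0, 2.0], rng.normal(5, 1, size=10)])
        res = group_compare(v, [True, True] + [False] * 10)
        assert res.test == "Mann–Whitney U"
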