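"""Rank tests, ROC, cutoff rules, confusion metrics, survival, logistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coxen import (
    ScoreVector,
    confusion_from_counts,
    confusion_metrics,
    km_logrank,
    logistic_adjusted,
    npv_max_cutoff,
    roc_auc,
    wilcoxon_rank_sum,
    youden_cutoff,
)
from coxen.evaluation import CutoffSpec, _candidate_thresholds, _counts_at, ppv_npv_curve

from conftest import make_clinical


def scores_of(values):
    vals = np.asarray(values, dtype=float)
    return ScoreVector([f"s{i}" for i in range(len(vals))], vals, z=vals)


class TestWilcoxon:
    def test_exact_small_sample(self):
        """{1,2} vs {3,4}: 6 equally likely rank assignments, the observed
        split is one extreme -> two-sided exact p = 1/3."""
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20) + 100
        b = rng.standard_normal(20)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestRocAuc:
    def test_hand_worked_example(self):
        sv = scores_of([0.1, 0.4, 0.35, 0.8])
        clin = make_clinical(sv.sample_ids, [0, 0, 1, 1])
        auc, lo, hi = roc_auc(sv, clin, n_boot=200, seed=0)
        assert auc == pytest.approx(0.75)
        assert lo <= auc <= hi

    def test_perfect_separation(self):
        sv = scores_of([0, 1, 2, 10, 11, 12])
        clin = make_clinical(sv.sample_ids, [0, 0, 0, 1, 1, 1])
        auc, _, _ = roc_auc(sv, clin, n_boot=50, seed=0)
        assert auc == 1.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10**6))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        s = np.round(rng.standard_normal(n), 1)  # coarse grid forces ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        sv = scores_of(s)
        clin = make_clinical(sv.sample_ids, y)
        auc, _, _ = roc_auc(sv, clin, n_boot=0, seed=0)
        pos, neg = s[y == 1], s[y == 0]
        pairs = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        sv = scores_of([1, 2, 3])
        clin = make_clinical(sv.sample_ids, [1, 1, 1])
        with pytest.raises(ValueError):
            roc_auc(sv, clin, n_boot=10, seed=0)


def brute_force_youden(s, y):
    best = None
    for thr in _candidate_thresholds(s):
        tp, fn, fp, tn = _counts_at(s, y, thr)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        key = (sens + spec - 1.0, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return best[1]


def brute_force_npv(s, y, min_neg):
    best = None
    for thr in _candidate_thresholds(s):
        tp, fn, fp, tn = _counts_at(s, y, thr)
        if tn + fn < min_neg:
            continue
        key = (tn / (tn + fn), tp / (tp + fn), -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return None if best is None else best[1]


class TestCutoffs:
    def test_separable_case(self):
        sv = scores_of([0.1, 0.2, 0.8, 0.9])
        clin = make_clinical(sv.sample_ids, [0, 0, 1, 1])
        spec = youden_cutoff(sv, clin)
        assert spec.youden_j == pytest.approx(1.0)
        assert spec.threshold == pytest.approx(0.5)
        nspec = npv_max_cutoff(sv, clin, min_predicted_negatives=2)
        assert nspec.npv == 1.0

    def test_youden_never_negative(self):
        sv = scores_of([0.9, 0.8, 0.2, 0.1])  # anti-predictive
        clin = make_clinical(sv.sample_ids, [0, 0, 1, 1])
        spec = youden_cutoff(sv, clin)
        assert spec.youden_j >= 0.0

    def test_all_equal_scores_degenerate(self):
        sv = scores_of([1.0, 1.0, 1.0, 1.0])
        clin = make_clinical(sv.sample_ids, [1, 1, 0, 0])
        spec = npv_max_cutoff(sv, clin, min_predicted_negatives=3)
        assert np.isinf(spec.threshold)  # only the all-negative rule qualifies

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            s = np.round(rng.standard_normal(n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            sv = scores_of(s)
            clin = make_clinical(sv.sample_ids, y)
            assert youden_cutoff(sv, clin).threshold == brute_force_youden(s, y)
            expected = brute_force_npv(s, y, 3)
            if expected is None:
                with pytest.raises(ValueError):
                    npv_max_cutoff(sv, clin)
            else:
                assert npv_max_cutoff(sv, clin).threshold == expected


class TestConfusionMetrics:
    def test_symmetric_table(self):
        m = confusion_from_counts(10, 10, 10, 10)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (0.5, 0.5, 0.5, 0.5)
        assert m.odds_ratio == 1.0

    def test_published_validation_cohort_row(self):
        """29/32 sensitive, 4/7 NPV — the platinum predictor's external
        validation counts reproduce with Wald intervals."""
        m = confusion_from_counts(29, 3, 19, 4)
        assert m.sensitivity == pytest.approx(0.906, abs=5e-4)
        assert m.sensitivity_ci[0] == pytest.approx(0.805, abs=1e-3)
        assert m.sensitivity_ci[1] == 1.0
        assert m.npv == pytest.approx(0.571, abs=5e-4)
        assert m.npv_ci == (pytest.approx(0.205, abs=1e-3), pytest.approx(0.938, abs=1e-3))

    def test_haldane_flag_on_zero_cell(self):
        m = confusion_from_counts(5, 0, 3, 2)
        assert m.haldane_corrected
        assert np.isfinite(m.odds_ratio)

    def test_undefined_margins_reported_as_nan(self):
        sv = scores_of([1.0, 2.0, 3.0])
        clin = make_clinical(sv.sample_ids, [1, 1, 0])
        m = confusion_metrics(sv, clin, CutoffSpec(-np.inf, "youden", 1, 0, 0, None))
        assert np.isnan(m.npv)  # nobody predicted negative

    def test_ppv_npv_curve_consistent(self):
        sv = scores_of([0.1, 0.2, 0.7, 0.9])
        clin = make_clinical(sv.sample_ids, [0, 1, 0, 1])
        curve = ppv_npv_curve(sv, clin)
        assert len(curve) == 5
        assert curve["sensitivity"].iloc[0] == 1.0  # -inf threshold


class TestSurvival:
    def test_median_of_full_follow_up(self):
        """All-event times 1..5: S(3) = 0.4 is the first drop below 1/2."""
        clin2 = make_clinical(
            list("abcdefghij"), [1] * 10,
            os_months=[1, 2, 3, 4, 5, 1, 2, 3, 4, 5], events=[True] * 10,
        )
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=clin2.sample_ids)
        res = km_logrank(clin2, groups, censor_horizon_months=100)
        assert res.medians["g1"] == pytest.approx(3.0)

    def test_km_without_censoring_is_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0]
        clin = make_clinical(
            list("abcdwxyz"), [1] * 8, os_months=times + [1.0, 1.0, 1.0, 1.0],
            events=[True] * 8,
        )
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=clin.sample_ids)
        res = km_logrank(clin, groups, censor_horizon_months=100)
        curve = res.curves["g1"].set_index("time")["survival"]
        for i, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1 - (i + 1) / 4)

    def test_matches_hand_computed_logrank(self):
        """Six subjects, one censored: chi-square agrees with the manual
        observed-minus-expected Mantel-Haenszel computation."""
        sample_ids = list("abcdef")
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, True, True, False, True]
        group = ["A", "B", "A", "B", "A", "B"]
        clin = make_clinical(sample_ids, [1] * 6, os_months=times, events=events)
        groups = pd.Series(group, index=sample_ids)
        res = km_logrank(clin, groups, censor_horizon_months=100)

        # manual: at each event time, O-E and hypergeometric variance for A
        o_minus_e, var = 0.0, 0.0
        at_risk = list(zip(times, events, group))
        for t, e, g in at_risk:
            if not e:
                continue
            risk = [(tt, gg) for tt, ee, gg in at_risk if tt >= t]
            n = len(risk)
            n_a = sum(1 for _, gg in risk if gg == "A")
            d = 1
            o_minus_e += (1 if g == "A" else 0) - d * n_a / n
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / max(n - 1, 1)
        chi2 = o_minus_e**2 / var
        assert res.logrank_statistic == pytest.approx(chi2, rel=1e-6)

    def test_horizon_censoring_applied(self):
        clin = make_clinical(
            list("abcdefgh"), [1] * 8,
            os_months=[10, 20, 90, 100, 15, 25, 95, 110],
            events=[True] * 8,
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=clin.sample_ids)
        res = km_logrank(clin, groups, censor_horizon_months=60)
        for curve in res.curves.values():
            assert curve["time"].max() <= 60


class TestLogistic:
    def test_two_by_two_slope_is_log_odds_ratio(self):
        """Counts (10,5,5,10) on a binary predictor: slope = ln 4."""
        ids = [f"p{i}" for i in range(30)]
        y = [1] * 10 + [0] * 5 + [1] * 5 + [0] * 10
        x = [1.0] * 15 + [0.0] * 15
        clin = make_clinical(ids, y)
        sv = ScoreVector(ids, np.asarray(x), z=np.asarray(x))
        table = logistic_adjusted(clin, sv)
        slope = table.loc[table["term"] == "score", "coefficient"].iloc[0]
        assert slope == pytest.approx(np.log(4.0), abs=1e-6)

    def test_null_score_p_uniformish(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(40):
            n = 200
            ids = [f"p{i}" for i in range(n)]
            y = rng.integers(0, 2, n)
            sv = ScoreVector(ids, rng.standard_normal(n))
            clin = make_clinical(ids, y)
            table = logistic_adjusted(clin, sv)
            pvals.append(table.loc[table["term"] == "score", "p_value"].iloc[0])
        assert abs(np.mean(np.asarray(pvals) < 0.5) - 0.5) < 0.2

    def test_planted_score_dominates_null_covariates(self):
        rng = np.random.default_rng(3)
        n = 300
        ids = [f"p{i}" for i in range(n)]
        score = rng.standard_normal(n)
        prob = 1 / (1 + np.exp(-2 * score))
        y = rng.random(n) < prob
        data = pd.DataFrame(
            {
                "response": np.where(y, "responder", "non_responder"),
                "os_months": 1.0,
                "event": True,
                "age": rng.normal(60, 8, n).round(1),
                "stage": rng.choice(["III", "IV"], n),
            },
            index=ids,
        )
        from coxen import ClinicalTable

        clin = ClinicalTable(data)
        sv = ScoreVector(ids, score)
        table = logistic_adjusted(clin, sv, covariates=["age", "stage"]).set_index("term")
        assert table.loc["score", "p_value"] < 1e-6
        assert table.loc["age", "p_value"] > 0.01

    def test_perfect_separation_raises(self):
        ids = [f"p{i}" for i in range(20)]
        y = [1] * 10 + [0] * 10
        sv = ScoreVector(ids, np.asarray([5.0] * 10 + [-5.0] * 10))
        clin = make_clinical(ids, y)
        with pytest.raises(ValueError):
            logistic_adjusted(clin, sv)
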