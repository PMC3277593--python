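"""Diagonal LDA, nested cross-validation and score combination."""

import numpy as np
import pandas as pd
import pytest

from coxen import (
    ScoreVector,
    SimulationConfig,
    combine_scores,
    double_cross_validate,
    fit_dlda,
    score_cohort,
    simulate_cell_panel,
    simulate_patient_cohort,
    select_extreme_lines,
)
from coxen.predictor import _dlda_predict, _rank_genes_by_t

from conftest import make_expression, make_labels


def gaussian_lr_oracle(x, mu_s, mu_r, var, pi_s, pi_r):
    """Log likelihood ratio of two diagonal Gaussians plus log prior odds."""
    x, mu_s, mu_r, var = (np.atleast_1d(np.asarray(v, float)) for v in (x, mu_s, mu_r, var))
    ll_s = -0.5 * np.sum((x - mu_s) ** 2 / var)
    ll_r = -0.5 * np.sum((x - mu_r) ** 2 / var)
    return ll_s - ll_r + np.log(pi_s / pi_r)


class TestFitDlda:
    def _toy_model(self, X_s, X_r, gene_ids=None):
        X = np.hstack([X_s, X_r])
        n_s = X_s.shape[1]
        expr = make_expression(X, gene_ids=gene_ids)
        labels = make_labels(
            [f"s{j}" for j in range(n_s)], [f"s{j}" for j in range(n_s, X.shape[1])]
        )
        return fit_dlda(expr, labels, expr.gene_ids)

    def test_midpoint_is_decision_boundary(self):
        # one gene, class means 2 vs 0, unit variance, equal priors
        from coxen import PredictorModel

        model = PredictorModel("toy", ["g0"], [2.0], [0.0], [1.0], 0.5, 0.5)
        assert model.discriminant(np.array([[1.0]]))[0] == pytest.approx(0.0, abs=1e-12)
        assert model.discriminant(np.array([[1.5]]))[0] > 0

    def test_matches_gaussian_likelihood_ratio_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X_s = rng.normal(1.0, 1.0, (3, 6))
            X_r = rng.normal(-0.5, 1.0, (3, 9))
            model = self._toy_model(X_s, X_r)
            x = rng.standard_normal(3)
            expected = gaussian_lr_oracle(
                x,
                model.mean_sensitive,
                model.mean_resistant,
                model.pooled_variance,
                model.prior_sensitive,
                model.prior_resistant,
            )
            got = model.discriminant(x[:, None])[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_label_swap_negates_discriminant(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 12))
        expr = make_expression(X)
        ids = expr.sample_ids
        labels = make_labels(ids[:6], ids[6:])
        swapped = make_labels(ids[6:], ids[:6])
        m1 = fit_dlda(expr, labels, expr.gene_ids)
        m2 = fit_dlda(expr, swapped, expr.gene_ids)
        x = rng.standard_normal((4, 5))
        assert np.allclose(m1.discriminant(x), -m2.discriminant(x), atol=1e-10)

    def test_zero_variance_gene_dropped(self):
        X = np.vstack([np.ones(10), np.random.default_rng(1).standard_normal(10)])
        expr = make_expression(X)
        labels = make_labels(expr.sample_ids[:5], expr.sample_ids[5:])
        model = fit_dlda(expr, labels, expr.gene_ids)
        assert model.gene_ids == ["g1"]

    def test_score_monotone_in_upregulated_gene(self):
        """Raising expression of a sensitive-up gene never lowers the score."""
        from coxen import PredictorModel

        model = PredictorModel("toy", ["up", "down"], [2.0, 0.0], [0.0, 2.0], [1.0, 1.0], 0.5, 0.5)
        x = np.array([[0.0], [1.0]])
        base = model.discriminant(x)[0]
        for delta in (0.5, 1.0, 10.0):
            bumped = x.copy()
            bumped[0, 0] += delta
            assert model.discriminant(bumped)[0] >= base


class TestDoubleCrossValidation:
    def test_perfectly_separable_panel(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 16)) * 0.1
        X[0, :8] += 10  # one decisive gene
        expr = make_expression(X)
        labels = make_labels(expr.sample_ids[:8], expr.sample_ids[8:])
        model = double_cross_validate(expr, labels, candidate_ks=(1, 5))
        assert model.cv_accuracy == 1.0
        assert "g0" in model.gene_ids

    def test_null_accuracy_near_half(self):
        accs = []
        for seed in range(25):
            cfg = SimulationConfig(
                n_genes=150, n_cell_lines=40, effect_size=0.0, n_concordant=0,
                n_patients=10, seed=seed,
            )
            expr, act, _ = simulate_cell_panel(cfg)
            labels = select_extreme_lines(act, 0.3)
            m = double_cross_validate(expr, labels, candidate_ks=(4, 8, 16))
            accs.append(m.cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.08

    def test_leaky_gene_selection_is_optimistic(self):
        """Ranking genes once on the full panel before leave-one-out CV
        (selection leakage) inflates null accuracy relative to the nested
        procedure, pairwise across seeds."""
        diffs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 16))
            y = np.array([1] * 8 + [0] * 8)
            expr = make_expression(X)
            labels = make_labels(expr.sample_ids[:8], expr.sample_ids[8:])
            nested = double_cross_validate(expr, labels, candidate_ks=(8,)).cv_accuracy

            leaky_order = _rank_genes_by_t(X, y)[:8]  # chosen on ALL samples
            correct = 0
            for i in range(16):
                mask = np.ones(16, bool)
                mask[i] = False
                pred = _dlda_predict(X[leaky_order][:, mask], y[mask], X[leaky_order, i])
                correct += int(pred == y[i])
            diffs.append(correct / 16 - nested)
        assert np.mean(diffs) > 0.05

    def test_fold_losing_a_class_rejected(self):
        expr = make_expression(np.random.default_rng(0).standard_normal((5, 6)))
        labels = make_labels(expr.sample_ids[:2], expr.sample_ids[2:])
        with pytest.raises(ValueError):
            double_cross_validate(expr, labels, candidate_ks=(2,))


class TestScoring:
    def test_degenerate_cohort_gets_zero_z(self):
        from coxen import PredictorModel

        model = PredictorModel("toy", ["g0"], [1.0], [0.0], [1.0], 0.5, 0.5)
        expr = make_expression(np.ones((1, 4)))
        scores = score_cohort(model, expr)
        assert np.allclose(scores.raw, scores.raw[0])
        assert np.allclose(scores.z, 0.0)

    def test_missing_genes_dropped_up_to_half(self):
        from coxen import PredictorModel

        model = PredictorModel(
            "toy", ["g0", "g1", "g2", "g3"], [1.0] * 4, [0.0] * 4, [1.0] * 4, 0.5, 0.5
        )
        rng = np.random.default_rng(2)
        expr = make_expression(rng.standard_normal((2, 5)), gene_ids=["g0", "g1"])
        scores = score_cohort(model, expr)
        assert len(scores.raw) == 5
        tiny = make_expression(rng.standard_normal((1, 5)), gene_ids=["g0"])
        with pytest.raises(ValueError):
            score_cohort(model, tiny)

    def test_planted_cohort_scores_separate_classes(self, small_config, small_panel, small_cohort):
        expr, act, _ = small_panel
        cohort_expr, clin, _ = small_cohort
        labels = select_extreme_lines(act, 0.3)
        model = double_cross_validate(expr, labels, candidate_ks=(5, 10))
        scores = score_cohort(model, cohort_expr)
        z = pd.Series(scores.z, index=scores.sample_ids)
        assert z[clin.responder_ids].mean() > z[clin.non_responder_ids].mean()

    def test_training_refit_is_at_least_as_good_as_cv(self, small_panel):
        expr, act, _ = small_panel
        labels = select_extreme_lines(act, 0.3)
        model = double_cross_validate(expr, labels, candidate_ks=(5, 10))
        scores = score_cohort(model, expr.subset_samples(labels.sample_ids))
        pred = np.where(scores.raw >= 0, "sensitive", "resistant")
        truth = labels.labels.loc[scores.sample_ids].to_numpy()
        assert (pred == truth).mean() >= model.cv_accuracy


class TestCombineScores:
    def test_identical_inputs_preserve_ordering(self):
        s = ScoreVector(["a", "b", "c"], [1.0, 2.0, 3.0])
        combo = combine_scores(s, s)
        assert np.allclose(np.corrcoef(combo.z, s.z)[0, 1], 1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = ScoreVector(list("abcdef"), rng.standard_normal(6))
        b = ScoreVector(list("abcdef"), rng.standard_normal(6))
        ab = combine_scores(a, b)
        ba = combine_scores(b, a)
        assert np.allclose(ab.z, ba.z, atol=1e-12)

    def test_unit_variance_before_restandardization(self):
        rng = np.random.default_rng(9)
        a = ScoreVector([f"s{i}" for i in range(5000)], rng.standard_normal(5000))
        b = ScoreVector([f"s{i}" for i in range(5000)], rng.standard_normal(5000))
        pre = (a.z + b.z) / np.sqrt(2.0)
        assert pre.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_sample_mismatch_rejected(self):
        a = ScoreVector(["a", "b"], [0.0, 1.0])
        b = ScoreVector(["b", "a"], [0.0, 1.0])
        with pytest.raises(ValueError):
            combine_scores(a, b)
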