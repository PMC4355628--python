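"""Diagnostic statistics against brute-force and library oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from qlus.stats import (
    ConfusionMatrix,
    cohen_kappa,
    combine_either,
    confusion,
    diagnostic_summary,
    friedman_test,
    rank_two_group_test,
    roc_analysis,
    signed_rank_test,
    spearman_rho,
    univariate_logistic,
)


def _labels_from_cm(cm):
    pred = [1] * cm.tp + [1] * cm.fp + [0] * cm.fn + [0] * cm.tn
    ref = [1] * cm.tp + [0] * cm.fp + [1] * cm.fn + [0] * cm.tn
    return np.array(pred), np.array(ref)


class TestConfusion:
    def test_cohort_counts_vs_ct(self, cohort64):
        ct = np.array(cohort64.column("ct_label"), dtype=bool)
        qlus = np.array([r.gray_units > 48 for r in cohort64])
        lus = np.array(cohort64.column("lus_label"), dtype=bool)
        cm_q = confusion(qlus, ct)
        assert (cm_q.tp, cm_q.fp, cm_q.fn, cm_q.tn) == (41, 1, 3, 19)
        cm_l = confusion(lus, ct)
        assert (cm_l.tp, cm_l.fp, cm_l.fn, cm_l.tn) == (30, 1, 14, 19)

    def test_identity_has_no_errors(self):
        y = np.array([1, 0, 1, 1, 0], dtype=bool)
        cm = confusion(y, y)
        assert cm.fp == cm.fn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1, 0, 1])


class TestSummaryAndKappa:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            # (tp, fp, fn, tn) -> rounded (S, Sp, PPV, NPV, DA)
            ((41, 1, 3, 19), (0.93, 0.95, 0.98, 0.86, 0.94)),
            ((28, 4, 16, 16), (0.64, 0.80, 0.88, 0.50, 0.69)),
            ((30, 1, 14, 19), (0.68, 0.95, 0.97, 0.58, 0.77)),
            ((10, 0, 0, 10), (1.0, 1.0, 1.0, 1.0, 1.0)),
        ],
    )
    def test_rounded_metrics(self, cm, expected):
        s = diagnostic_summary(ConfusionMatrix(*cm)).rounded()
        assert (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy) == expected

    @pytest.mark.parametrize(
        "cm, expected_rounded",
        [((30, 1, 14, 19), 0.54), ((28, 4, 16, 16), 0.38), ((10, 0, 0, 10), 1.0)],
    )
    def test_kappa_rounded(self, cm, expected_rounded):
        k = cohen_kappa(ConfusionMatrix(*cm)).value
        assert round(k, 2) == expected_rounded

    def test_kappa_bands(self):
        assert cohen_kappa(ConfusionMatrix(30, 1, 14, 19)).band == "moderate"
        assert cohen_kappa(ConfusionMatrix(41, 1, 3, 19)).band == "almost perfect"
        assert cohen_kappa(ConfusionMatrix(28, 4, 16, 16)).band == "fair"

    def test_undefined_metric_flagged_not_zero(self):
        s = diagnostic_summary(ConfusionMatrix(0, 0, 5, 5))
        assert s.ppv is None
        assert s.sensitivity == 0.0

    def test_against_brute_force_and_sklearn(self):
        """Summary and kappa agree with direct recomputation from label vectors."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            counts = rng.integers(0, 12, size=4)
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(*map(int, counts))
            pred, ref = _labels_from_cm(cm)
            s = diagnostic_summary(cm)
            assert s.accuracy == pytest.approx(np.mean(pred == ref))
            if cm.n_positive:
                assert s.sensitivity == pytest.approx(pred[ref == 1].mean())
            if cm.n_negative:
                assert s.specificity == pytest.approx(1 - pred[ref == 0].mean())
            k = cohen_kappa(cm).value
            if k is not None and len(np.unique(pred)) == 2 and len(np.unique(ref)) == 2:
                assert k == pytest.approx(cohen_kappa_score(pred, ref), abs=1e-12)


class TestCombineEither:
    def test_cohort_combined_counts(self, cohort64):
        ct = np.array(cohort64.column("ct_label"), dtype=bool)
        either = combine_either(cohort64.column("cxr_label"), cohort64.column("lus_label"))
        cm = confusion(either, ct)
        assert (cm.tp, cm.fp) == (34, 5)

    def test_idempotent_and_dominant(self):
        a = np.array([1, 0, 1, 0], dtype=bool)
        assert (combine_either(a, a) == a).all()
        assert combine_either(np.zeros(3, bool), np.ones(3, bool)).all()


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.best_youden == pytest.approx(1.0)

    def test_all_tied_scores(self):
        roc = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_auc_equals_pairwise_oracle(self):
        """AUC equals concordant-pair proportion (+ half ties), brute force."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 10, size=n).astype(float)
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            pos, neg = scores[y], scores[~y]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            oracle = np.mean(pairs)
            roc = roc_analysis(scores, y)
            assert roc.auc == pytest.approx(oracle, abs=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_youden_cutoff_beats_every_observed_threshold(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(3, 1, 40), rng.normal(5, 1, 40)])
        y = np.repeat([False, True], 40)
        roc = roc_analysis(scores, y)
        best_j = roc.best_youden
        for t in np.unique(scores):
            sens = np.mean(scores[y] > t)
            spec = np.mean(scores[~y] <= t)
            assert sens + spec - 1 <= best_j + 1e-12

    def test_hanley_mcneil_se_closed_form(self):
        roc = roc_analysis([1, 2, 3, 4, 10, 11], [0, 0, 0, 0, 1, 1])
        a, n1, n0 = roc.auc, 2, 4
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
        assert roc.se == pytest.approx(math.sqrt(var))

    def test_sensitivity_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 50, 60).astype(float)
        y = rng.integers(0, 2, 60).astype(bool)
        roc = roc_analysis(scores, y)
        assert (np.diff(roc.sensitivities) <= 1e-12).all()


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]).rho == pytest.approx(1.0)

    def test_cohort_gu_volume_correlation_positive(self, fixture_table):
        pos = [r for r in fixture_table if r.ct_label]
        res = spearman_rho([r.nonaerated_volume_ml for r in pos],
                           [r.gray_units for r in pos])
        assert res.rho > 0.5 and res.p_value < 0.001

    def test_cohort_gu_distance_correlation_negative(self, fixture_table):
        pos = [r for r in fixture_table if r.ct_label]
        res = spearman_rho([r.distance_from_pleura_mm for r in pos],
                           [r.gray_units for r in pos])
        assert res.rho < -0.3 and res.p_value < 0.01

    def test_null_distribution_centered_on_zero(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(1000).astype(float)
        y = rng.permutation(1000).astype(float)
        res = spearman_rho(x, y)
        se = 1 / math.sqrt(len(x) - 1)
        assert abs(res.rho) < 3 * se

    def test_zero_variance_flagged(self):
        assert spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]).undefined


class TestRankTests:
    def test_cohort_groups_differ(self, cohort64):
        pos = [r.gray_units for r in cohort64 if r.ct_label]
        neg = [r.gray_units for r in cohort64 if not r.ct_label]
        res = rank_two_group_test(pos, neg)
        assert res.p_value < 0.001
        assert np.median(pos) > np.median(neg)

    def test_identical_groups_null(self):
        res = rank_two_group_test([1.0, 2.0, 3.0, 7.0], [1.0, 2.0, 3.0, 7.0])
        assert res.p_value > 0.9

    def test_exact_p_matches_enumeration_oracle(self):
        """Small-sample exact p equals brute-force enumeration over rank splits."""
        a = [1.0, 4.0, 6.0, 9.0, 12.0]
        b = [2.0, 3.0, 8.0, 15.0, 20.0]
        res = rank_two_group_test(a, b)
        assert res.method == "exact"
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        n_a = len(a)
        u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        u_all = []
        for comb in itertools.combinations(range(len(pooled)), n_a):
            u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
            u_all.append(u)
        u_all = np.array(u_all)
        mean_u = n_a * len(b) / 2
        p_exact = np.mean(np.abs(u_all - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_signed_rank_and_friedman_run(self):
        before = [10.0, 12.0, 9.0, 14.0, 11.0, 13.0]
        after = [11.5, 13.0, 10.0, 17.0, 12.0, 15.0]
        assert signed_rank_test(before, after).p_value < 0.1
        g = [[1, 2, 3, 4, 5.0], [2, 3, 4, 5, 6.0], [1.5, 2.5, 3.5, 4.5, 5.5]]
        res = friedman_test(*g)
        assert 0 <= res.p_value <= 1
        with pytest.raises(ValueError):
            friedman_test([1.0, 2.0], [2.0, 3.0])


class TestLogistic:
    @staticmethod
    def _simulate(rng, n=500, beta=0.08, intercept=-2.0):
        x = rng.uniform(0, 60, n)
        p = 1 / (1 + np.exp(-(intercept + beta * x)))
        y = rng.random(n) < p
        return y, x

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(2024)
        y, x = self._simulate(rng)
        fit = univariate_logistic(y, x)
        assert fit.converged and not fit.separation
        assert fit.beta == pytest.approx(0.08, abs=3 * fit.beta_se)
        assert fit.ci_low < fit.odds_ratio < fit.ci_high
        assert fit.gof_p > 0.001  # correctly specified model should fit

    def test_constant_predictor_degenerate(self):
        fit = univariate_logistic([0, 1, 0, 1], [5.0, 5.0, 5.0, 5.0])
        assert fit.separation and "constant" in fit.message

    def test_single_outcome_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            univariate_logistic([1, 1, 1], [1.0, 2.0, 3.0])

    def test_complete_separation_flagged(self):
        fit = univariate_logistic([0, 0, 0, 1, 1, 1], [1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        assert fit.separation
        assert "separation" in fit.message
        assert fit.beta is None

    def test_cohort_volume_separates_qlus_within_ct_positive(self, fixture_table):
        """Within CT-positive rows, volume perfectly separates the QLUS call."""
        pos = [r for r in fixture_table if r.ct_label]
        y = [r.gray_units > 48 for r in pos]
        x = [r.nonaerated_volume_ml for r in pos]
        fit = univariate_logistic(y, x)
        assert fit.separation
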