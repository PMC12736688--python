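"""Confusion metrics, kappa, McNemar test, probability summaries."""

import numpy as np
import pytest
from scipy.stats import chi2, norm
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             precision_score, recall_score)
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ricesits.evaluation import (ConfusionCounts, area_agreement_ratio,
                                 bonferroni, classification_metrics,
                                 confusion_counts, mcnemar_chi2,
                                 mcnemar_test, probability_summary)


def vectors_from_counts(cm: ConfusionCounts):
    y = np.r_[np.ones(cm.tp + cm.fn, int), np.zeros(cm.tn + cm.fp, int)]
    p = np.r_[np.ones(cm.tp, int), np.zeros(cm.fn, int),
              np.zeros(cm.tn, int), np.ones(cm.fp, int)]
    return y, p


class TestConfusionCounts:
    def test_perfect_prediction(self):
        cm = confusion_counts([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0 and cm.tp == 2 and cm.tn == 1

    def test_enumeration(self):
        cm = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_inversion_swaps_quadrants(self):
        y = np.array([1, 1, 1, 0, 0])
        p = np.array([1, 0, 1, 0, 1])
        a = confusion_counts(y, p)
        b = confusion_counts(y, 1 - p)
        assert (a.tp, a.fn) == (b.fn, b.tp)
        assert (a.fp, a.tn) == (b.tn, b.fp)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([0, 2], [0, 1])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        a = confusion_counts(y, p)
        b = confusion_counts(y[perm], p[perm])
        assert a == b


class TestMetrics:
    def test_reported_test_set_row(self):
        """The held-out confusion matrix (2936 rice / 2866 non-rice correct
        of 6000, recall 0.979) yields the published metric set and validates
        the standard kappa form."""
        cm = ConfusionCounts(tp=2936, tn=2866, fp=135, fn=63)
        m = classification_metrics(cm)
        assert round(m["accuracy"], 3) == 0.967
        assert round(m["precision"], 3) == 0.956
        assert round(m["recall"], 3) == 0.979
        assert round(m["f1"], 3) == 0.967
        assert round(m["kappa"], 3) == 0.934

    def test_matches_sklearn(self):
        cm = ConfusionCounts(tp=37, tn=52, fp=9, fn=14)
        y, p = vectors_from_counts(cm)
        m = classification_metrics(cm)
        assert m["accuracy"] == pytest.approx(accuracy_score(y, p))
        assert m["precision"] == pytest.approx(precision_score(y, p))
        assert m["recall"] == pytest.approx(recall_score(y, p))
        assert m["f1"] == pytest.approx(f1_score(y, p))
        assert m["kappa"] == pytest.approx(cohen_kappa_score(y, p))

    def test_chance_agreement_kappa_zero(self):
        m = classification_metrics(ConfusionCounts(10, 10, 10, 10))
        assert m["kappa"] == pytest.approx(0.0)

    def test_perfect_matrix(self):
        m = classification_metrics(ConfusionCounts(5, 5, 0, 0))
        for k in ("accuracy", "precision", "recall", "f1", "kappa"):
            assert m[k] == pytest.approx(1.0)

    def test_kappa_identity_at_balanced_marginals(self):
        # Pe = 0.5 when both marginals are balanced: kappa = 2(Po - 0.5)
        cm = ConfusionCounts(tp=30, tn=30, fp=20, fn=20)
        m = classification_metrics(cm)
        assert m["pe"] == pytest.approx(0.5)
        assert m["kappa"] == pytest.approx(2 * (m["accuracy"] - 0.5))

    def test_undefined_ratios_flagged(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=2))
        assert m["precision"] is None and "precision" in m["undefined"]


class TestMcNemar:
    def test_chi2_from_counts(self):
        assert mcnemar_chi2(206, 80) == pytest.approx(125 ** 2 / 286)
        assert mcnemar_chi2(10, 2) == pytest.approx(49 / 12)
        assert mcnemar_chi2(10, 2, continuity=False) == pytest.approx(64 / 12)

    def test_p_value_arithmetic(self):
        stat = 49 / 12
        assert float(chi2.sf(stat, 1)) == pytest.approx(0.0433, abs=2e-4)

    def test_identical_predictions(self):
        y = np.array([0, 1, 1, 0])
        res = mcnemar_test(y, y, y)
        assert res.b == res.c == 0 and res.p_value == 1.0

    def test_discordant_counting(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        a = np.array([1, 1, 0, 0, 0, 1])   # correct on 1,2,4,5
        b = np.array([1, 0, 0, 0, 1, 1])   # correct on 1,3(no)...
        res = mcnemar_test(y, a, b)
        a_ok = a == y
        b_ok = b == y
        assert res.b == int((a_ok & ~b_ok).sum())
        assert res.c == int((~a_ok & b_ok).sum())

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 400)
        a = np.where(rng.random(400) < 0.85, y, 1 - y)
        b = np.where(rng.random(400) < 0.7, y, 1 - y)
        res = mcnemar_test(y, a, b, continuity=True)
        table = np.array([[0, res.b], [res.c, 0]])
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert res.chi2 == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_uncorrected_equals_squared_standardised_difference(self):
        b, c = 37, 18
        z = (b - c) / np.sqrt(b + c)
        assert mcnemar_chi2(b, c, continuity=False) == pytest.approx(z ** 2)

    def test_bonferroni(self):
        adj = bonferroni([0.01, 0.2], n_tests=6)
        assert np.allclose(adj, [0.06, 1.0])


class TestAreaAgreement:
    def test_reported_ratio(self):
        assert area_agreement_ratio(4.031e4, 4.394e4) == \
            pytest.approx(91.74, abs=0.005)

    def test_symmetric(self):
        assert area_agreement_ratio(2, 1) == area_agreement_ratio(1, 2)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            area_agreement_ratio(0, 1)


class TestProbabilitySummary:
    def test_perfect_separation_zero_overlap(self):
        p = np.r_[np.full(50, 0.05), np.full(50, 0.95)]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        assert probability_summary(p, y)["overlap"] == pytest.approx(0.0)

    def test_identical_distributions_full_overlap(self):
        rng = np.random.default_rng(0)
        vals = rng.random(500)
        p = np.r_[vals, vals]
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        assert probability_summary(p, y)["overlap"] == pytest.approx(1.0)

    def test_gaussian_overlap_matches_quadrature(self):
        """Two clipped Gaussians: histogram overlap approximates the
        integral of the pointwise minimum of the densities."""
        rng = np.random.default_rng(1)
        n = 200_000
        a = np.clip(rng.normal(0.3, 0.08, n), 0, 1)
        b = np.clip(rng.normal(0.6, 0.08, n), 0, 1)
        p = np.r_[a, b]
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        est = probability_summary(p, y, bins=50)["overlap"]
        grid = np.linspace(0, 1, 20_001)
        fa = norm.pdf(grid, 0.3, 0.08)
        fb = norm.pdf(grid, 0.6, 0.08)
        ref = np.trapezoid(np.minimum(fa, fb), grid)
        assert est == pytest.approx(ref, abs=0.03)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            probability_summary([1.2], [1])
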