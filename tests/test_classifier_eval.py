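"""Naive Bayes and the four accuracy criteria, with independent oracles
(brute-force pair counting for AUC, hand Bayes-rule arithmetic for the
classifier, statsmodels/sklearn as cross-checks)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mimofilter.classifier_eval import (
    ProbPrediction,
    auc,
    compare_classifiers,
    f_score,
    holm_adjust,
    metrics_report,
    nb_fit_predict,
    rmse,
    sar,
)


def brute_force_auc(scores, labels):
    """O(n^2) concordant-pair fraction, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestNaiveBayes:
    def test_separable_clusters(self, rng):
        X0 = rng.standard_normal((100, 3)) - 4
        X1 = rng.standard_normal((100, 3)) + 4
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 100)
        test = np.vstack([rng.standard_normal((50, 3)) - 4, rng.standard_normal((50, 3)) + 4])
        test_y = np.repeat([0, 1], 50)
        pred = nb_fit_predict(X, y, test)
        assert auc(pred.probs, test_y) > 0.99

    def test_null_features_give_chance_auc(self, rng):
        aucs = []
        for _ in range(30):
            X = rng.standard_normal((120, 4))
            y = (rng.standard_normal(120) > 0).astype(int)
            if min(y.sum(), 120 - y.sum()) < 3:
                continue
            pred = nb_fit_predict(X[:60], y[:60], X[60:])
            aucs.append(auc(pred.probs, y[60:]))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_hand_computed_posteriors(self):
        # 4 training samples, 1 feature, variance 0.25 in both classes
        train = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        test = np.array([[1.5], [0.5]])
        pred = nb_fit_predict(train, y, test)
        def manual(x):
            like = []
            for mu in (0.5, 2.5):  # class means, var 0.25, priors 1/2
                like.append(stats.norm.pdf(x, mu, 0.5))
            return like[1] / (like[0] + like[1])
        assert pred.probs[0] == pytest.approx(manual(1.5), rel=1e-9)
        assert pred.probs[1] == pytest.approx(manual(0.5), rel=1e-9)

    def test_duplicated_feature_shifts_posterior(self):
        # naive independence double-counts a duplicated column
        train = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        test = np.array([[2.2]])
        p1 = nb_fit_predict(train, y, test).probs[0]
        p2 = nb_fit_predict(np.hstack([train, train]), y, np.array([[2.2, 2.2]])).probs[0]
        assert p2 > p1  # evidence counted twice
        # hand value: posterior odds squared
        odds = p1 / (1 - p1)
        assert p2 == pytest.approx(odds**2 / (1 + odds**2), rel=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        X = rng.standard_normal((60, 5))
        y = (rng.standard_normal(60) > 0).astype(int)
        pred = nb_fit_predict(X[:40], y[:40], X[40:])
        assert np.all((pred.probs >= 0) & (pred.probs <= 1))

    def test_matches_sklearn(self, rng):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.standard_normal((80, 4))
        y = (X[:, 0] + rng.standard_normal(80) > 0).astype(int)
        mine = nb_fit_predict(X[:50], y[:50], X[50:]).probs
        ref = sklearn_nb.GaussianNB(var_smoothing=0.0)
        ref.fit(X[:50], y[:50])
        theirs = ref.predict_proba(X[50:])[:, 1]
        assert np.allclose(mine, theirs, atol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nb_fit_predict(rng.standard_normal((10, 2)), np.zeros(10), rng.standard_normal((3, 2)))


class TestAUC:
    def test_perfect_and_tied(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_enumeration(self, rng):
        for _ in range(60):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            labels = (rng.standard_normal(n) > 0).astype(int)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), rel=1e-12
            )

    def test_complement_identity_tie_free(self, rng):
        scores = rng.standard_normal(40)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestScalarMetrics:
    def test_rmse_cases(self):
        assert rmse([0, 1, 1], [0, 1, 1]) == 0.0
        assert rmse([0.5] * 4, [0, 1, 0, 1]) == 0.5
        assert rmse([0.8, 0.3], [1, 0]) == pytest.approx(np.sqrt((0.04 + 0.09) / 2))

    def test_sar_is_exact_mean(self):
        assert sar(1.0, 1.0, 0.0) == 1.0
        assert sar(0.5, 0.5, 0.5) == 0.5
        assert sar(0.8, 0.7, 0.4) == pytest.approx(0.7)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_sar_identity(self, a, u, r):
        assert sar(a, u, r) == pytest.approx((a + u + (1 - r)) / 3, rel=1e-12)

    def test_f_score_cases(self):
        assert f_score([1, 0, 1], [1, 0, 1]) == 1.0
        assert f_score([0, 0, 0], [1, 0, 1]) == 0.0
        # TP=2, FP=1, FN=1
        assert f_score([1, 1, 1, 0, 0], [1, 1, 0, 1, 0]) == pytest.approx(2 / 3)

    def test_metrics_report_consistency(self, rng):
        probs = rng.uniform(0, 1, 50)
        y = (rng.standard_normal(50) > 0).astype(int)
        rep = metrics_report(ProbPrediction(probs), y)
        assert rep.one_minus_rmse == pytest.approx(1 - rmse(probs, y))
        acc = np.mean((probs >= 0.5).astype(int) == y)
        assert rep.sar == pytest.approx(sar(acc, rep.auc, 1 - rep.one_minus_rmse))


class TestCompareClassifiers:
    def test_identical_classifiers_p_one(self):
        err = np.array([1, 0, 0, 1, 0], bool)
        sq = np.array([0.1, 0.2, 0.0, 0.4, 0.1])
        assert compare_classifiers(err, err, sq, sq) == (1.0, 1.0)

    def test_one_sided_discordance_binomial_tail(self):
        # A always right, B wrong on 20 of 40: exact two-sided binomial, k=0
        errA = np.zeros(40, bool)
        errB = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        p_mc, _ = compare_classifiers(errA, errB, np.zeros(40), errB.astype(float))
        assert p_mc == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_symmetric_discordance_p_one(self):
        errA = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        errB = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        p_mc, _ = compare_classifiers(errA, errB, errA.astype(float), errB.astype(float))
        assert p_mc == pytest.approx(1.0)

    def test_wilcoxon_detects_systematic_gap(self, rng):
        sqA = rng.uniform(0, 0.2, 60)
        sqB = sqA + 0.3
        _, p_wx = compare_classifiers(
            np.zeros(60, bool), np.zeros(60, bool), sqA, sqB
        )
        assert p_wx < 1e-6


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_worked_example(self):
        # sorted (0.01, 0.03, 0.04): 3*0.01=0.03; max(0.03, 2*0.03)=0.06;
        # max(0.06, 1*0.04)=0.06
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_equal_ps(self):
        assert np.allclose(holm_adjust([0.02] * 4), [0.08] * 4)

    def test_matches_statsmodels(self, rng):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 12)))
            mine = holm_adjust(p)
            theirs = multipletests(p, method="holm")[1]
            assert np.allclose(mine, theirs, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_never_anticonservative_and_order_preserving(self, pvals):
        p = np.asarray(pvals)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
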