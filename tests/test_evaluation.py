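"""ROC/PR/Youden/threshold metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thgqc.evaluation import (
    CurveBundle,
    ScoredSet,
    UndefinedMetricError,
    aggregate_curves,
    evaluate_ensemble,
    metrics_at_threshold,
    no_skill_ap,
    pr_ap,
    roc_auc,
    youden_threshold,
)


def pairwise_concordance_auc(scores, labels):
    """Mann-Whitney oracle: concordant pairs + half ties over all pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_ap(scores, labels):
    """AP by explicit threshold enumeration (score >= t -> positive)."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = labels.sum()
    last_recall = 0.0
    ap = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - last_recall) * precision
        last_recall = recall
    return ap


scored_sets = st.integers(min_value=2, max_value=60).flatmap(
    lambda n: st.tuples(
        st.lists(st.sampled_from([round(x * 0.05, 2) for x in range(21)]),
                 min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)),
    )
)


class TestRocAuc:
    def test_perfect_separation(self):
        s = ScoredSet(scores=np.array([0.1, 0.2, 0.8, 0.9]),
                      labels=np.array([0, 0, 1, 1]))
        assert roc_auc(s).auc == pytest.approx(1.0)

    def test_four_point_fixture_matches_concordance(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        res = roc_auc(ScoredSet(scores=scores, labels=labels))
        assert res.auc == pytest.approx(
            pairwise_concordance_auc(scores, labels))  # = 3/4

    def test_constant_scores_give_half(self):
        s = ScoredSet(scores=np.full(6, 0.5),
                      labels=np.array([0, 1, 0, 1, 0, 1]))
        assert roc_auc(s).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(ScoredSet(scores=np.array([0.2, 0.3]),
                              labels=np.array([1, 1])))

    def test_curve_monotone_nondecreasing(self, rng):
        s = ScoredSet(scores=rng.random(50),
                      labels=rng.integers(0, 2, 50))
        res = roc_auc(s)
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(scored_sets)
    def test_auc_equals_mann_whitney_everywhere(self, data):
        scores, labels = np.array(data[0]), np.array(data[1])
        res = roc_auc(ScoredSet(scores=scores, labels=labels))
        assert res.auc == pytest.approx(
            pairwise_concordance_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            scores = rng.random(40).round(1)  # force ties
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            assert roc_auc(
                ScoredSet(scores=scores, labels=labels)
            ).auc == pytest.approx(roc_auc_score(labels, scores))


class TestAveragePrecision:
    def test_no_skill_baseline_prints_048(self):
        assert no_skill_ap(60, 124) == pytest.approx(0.48, abs=0.005)

    def test_perfect_ranking(self):
        s = ScoredSet(scores=np.array([0.9, 0.8, 0.2, 0.1]),
                      labels=np.array([1, 1, 0, 0]))
        assert pr_ap(s).average_precision == pytest.approx(1.0)

    def test_two_point_enumeration(self):
        s = ScoredSet(scores=np.array([0.9, 0.1]), labels=np.array([1, 0]))
        res = pr_ap(s)
        assert res.average_precision == pytest.approx(
            brute_force_ap(s.scores, s.labels))  # = 1.0

    def test_zero_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pr_ap(ScoredSet(scores=np.array([0.5]), labels=np.array([0])))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(scored_sets)
    def test_ap_matches_threshold_enumeration(self, data):
        scores, labels = np.array(data[0]), np.array(data[1])
        res = pr_ap(ScoredSet(scores=scores, labels=labels))
        assert res.average_precision == pytest.approx(
            brute_force_ap(scores, labels), abs=1e-12)


class TestYouden:
    def test_gap_fixture_returns_lowest_qualifying_score(self):
        s = ScoredSet(scores=np.array([0.1, 0.2, 0.7, 0.8]),
                      labels=np.array([0, 0, 1, 1]))
        assert youden_threshold(roc_auc(s)) == pytest.approx(0.7)

    def test_constant_scores_warn_and_return_lowest(self):
        s = ScoredSet(scores=np.full(4, 0.3), labels=np.array([0, 1, 0, 1]))
        with pytest.warns(UserWarning, match="no .or inverted."):
            thr = youden_threshold(roc_auc(s))
        assert thr == pytest.approx(0.3)

    def test_anticorrelated_scores_warn(self):
        s = ScoredSet(scores=np.array([0.9, 0.8, 0.2, 0.1]),
                      labels=np.array([0, 0, 1, 1]))
        with pytest.warns(UserWarning):
            youden_threshold(roc_auc(s))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(scored_sets)
    def test_returned_threshold_maximizes_j_exhaustively(self, data):
        scores, labels = np.array(data[0]), np.array(data[1])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = youden_threshold(roc_auc(ScoredSet(scores=scores,
                                                     labels=labels)))

        def j_at(t):
            pred = scores >= t
            tpr = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
            fpr = (pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
            return tpr - fpr

        j_ret = j_at(thr)
        for t in np.unique(scores):
            assert j_ret >= j_at(t) - 1e-12
            # tie-break: no smaller candidate achieves the same maximal J
            if t < thr:
                assert j_at(t) < j_ret - 1e-12


class TestMetricsAtThreshold:
    def test_clean_split(self):
        s = ScoredSet(scores=np.array([0.4, 0.6]), labels=np.array([0, 1]))
        m = metrics_at_threshold(s, 0.5)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_threshold_zero_predicts_all_positive(self):
        s = ScoredSet(scores=np.array([0.2, 0.9, 0.4]),
                      labels=np.array([0, 1, 1]))
        m = metrics_at_threshold(s, 0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_confusion_counts_match_direct_tallies(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            thr = float(rng.random())
            m = metrics_at_threshold(ScoredSet(scores=scores, labels=labels),
                                     thr)
            tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
            fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
            fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
            tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
            assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
            assert m.accuracy == pytest.approx((tp + tn) / n)

    def test_accuracy_between_sens_and_spec_weighted(self, rng):
        # arithmetic identity: acc = prev*sens + (1-prev)*spec
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        s = ScoredSet(scores=scores, labels=labels)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = youden_threshold(roc_auc(s))
        m = metrics_at_threshold(s, thr)
        prev = labels.mean()
        assert m.accuracy == pytest.approx(
            prev * m.sensitivity + (1 - prev) * m.specificity)


class TestAggregateCurves:
    def test_identical_members_zero_variance(self):
        x = np.linspace(0, 1, 11)
        y = x**2
        bundle = aggregate_curves([(x, y)] * 10, [0.5] * 10)
        assert np.allclose(bundle.variance, 0.0)
        assert np.allclose(bundle.mean, np.interp(bundle.grid, x, y))

    def test_mean_between_two_ordered_members(self):
        x = np.linspace(0, 1, 21)
        lo, hi = x * 0.5, np.minimum(x * 2, 1.0)
        bundle = aggregate_curves([(x, lo), (x, hi)], [0.25, 0.9])
        interior = (bundle.grid > 0.05) & (bundle.grid < 0.45)
        lo_i = np.interp(bundle.grid, x, lo)
        hi_i = np.interp(bundle.grid, x, hi)
        assert (bundle.mean[interior] > lo_i[interior]).all()
        assert (bundle.mean[interior] < hi_i[interior]).all()

    def test_reported_scalar_is_mean_of_member_scalars(self, rng):
        curves, scalars = [], []
        for seed in range(3):
            r = np.random.default_rng(seed)
            s = ScoredSet(scores=r.random(30), labels=r.integers(0, 2, 30))
            roc = roc_auc(s)
            curves.append((roc.fpr, roc.tpr))
            scalars.append(roc.auc)
        bundle = aggregate_curves(curves, scalars)
        assert bundle.mean_scalar == pytest.approx(np.mean(scalars))
        integrated = np.trapezoid(bundle.mean, bundle.grid)
        # the integrated mean curve is a different quantity
        assert bundle.mean_scalar != pytest.approx(integrated, abs=1e-12)

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            aggregate_curves([(np.array([0, 1]), np.array([0, 1]))], [0.5])


def test_evaluate_ensemble_summary_keys(rng):
    sets = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        scores = np.clip(labels * 0.4 + r.random(20) * 0.5, 0, 1)
        sets.append(ScoredSet(scores=scores, labels=labels))
    out = evaluate_ensemble(sets)
    assert set(out["mean"]) == {"auc", "average_precision", "accuracy",
                                "sensitivity", "specificity",
                                "youden_threshold"}
    assert isinstance(out["roc_bundle"], CurveBundle)
    assert 0.5 < out["mean"]["auc"] <= 1.0
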