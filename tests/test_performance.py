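"""ROC / precision-recall metrics, bootstrap CIs, and paired comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.metrics import average_precision_score, roc_auc_score

from solmark.performance import (
    ScoreLabelSet,
    auroc,
    average_precision,
    bootstrap_ci,
    compare_to_reference,
    delong_auroc_test,
    f1_max,
)


def brute_force_auroc(scores, labels):
    """Pair-enumeration oracle: wins + half ties over all pos-neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.7, 0.4], [1, 1, 0, 0], 1.0),
            ([3, 2, 1], [1, 0, 1], 0.5),
            ([1, 1], [1, 0], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auroc(ScoreLabelSet(scores, labels)) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        scores=hst.lists(hst.integers(0, 3), min_size=2, max_size=12),
        data=hst.data(),
    )
    def test_matches_pair_enumeration_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            hst.lists(hst.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        s = ScoreLabelSet(scores, labels)
        assert auroc(s) == pytest.approx(brute_force_auroc(scores, labels))

    def test_matches_sklearn_on_random_scores(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        s = ScoreLabelSet(scores, labels)
        assert auroc(s) == pytest.approx(roc_auc_score(labels, scores))

    def test_low_orientation_negates(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.3).astype(int)
        labels[:2] = [0, 1]
        hi = auroc(ScoreLabelSet(scores, labels, orientation="high"))
        lo = auroc(ScoreLabelSet(scores, labels, orientation="low"))
        assert hi + lo == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ScoreLabelSet([1.0, 2.0], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        ap, base = average_precision(ScoreLabelSet([4, 3, 2, 1], [1, 1, 0, 0]))
        assert ap == pytest.approx(1.0)
        assert base == pytest.approx(0.5)

    def test_one_positive_ranked_second(self):
        ap, _ = average_precision(ScoreLabelSet([1.0, 0.0], [0, 1]))
        assert ap == pytest.approx(0.5)

    def test_baseline_equals_prevalence(self):
        scores = np.arange(205, dtype=float)
        labels = np.r_[np.ones(9, int), np.zeros(196, int)]
        _, base = average_precision(ScoreLabelSet(scores, labels))
        assert base == pytest.approx(9 / 205)

    def test_matches_sklearn_average_precision(self, rng):
        scores = rng.normal(size=150)
        labels = (rng.random(150) < 0.25).astype(int)
        labels[:2] = [0, 1]
        ap, _ = average_precision(ScoreLabelSet(scores, labels))
        assert ap == pytest.approx(average_precision_score(labels, scores), rel=1e-12)


class TestF1Max:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([4, 3, 2, 1], [1, 1, 0, 0], 1.0),
            ([3, 2, 1], [1, 0, 1], 0.8),  # max of {2/3, 1/2, 4/5}
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert f1_max(ScoreLabelSet(scores, labels)) == pytest.approx(expected)

    def test_lowest_threshold_closed_form(self, rng):
        # predicting everything positive gives F1 = 2 prev / (1 + prev),
        # a lower bound attained at the lowest threshold
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.2).astype(int)
        labels[:2] = [0, 1]
        s = ScoreLabelSet(scores, labels)
        prev = s.prevalence
        assert f1_max(s) >= 2 * prev / (1 + prev) - 1e-12


class TestInvariances:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=hst.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(int)
        labels[:2] = [0, 1]
        a = ScoreLabelSet(scores, labels)
        b = ScoreLabelSet(np.exp(2.0 * scores) + 5.0, labels)  # strictly increasing
        assert auroc(a) == pytest.approx(auroc(b))
        assert average_precision(a)[0] == pytest.approx(average_precision(b)[0])
        assert f1_max(a) == pytest.approx(f1_max(b))

    def test_perfect_separation_bundle(self, rng):
        pos = rng.uniform(5, 6, 12)
        neg = rng.uniform(0, 1, 30)
        s = ScoreLabelSet(np.r_[pos, neg], np.r_[np.ones(12, int), np.zeros(30, int)])
        assert auroc(s) == 1.0
        assert average_precision(s)[0] == pytest.approx(1.0)
        assert f1_max(s) == pytest.approx(1.0)


class TestBootstrap:
    def test_degenerate_metric_gives_point_ci(self):
        s = ScoreLabelSet([5, 4, 1, 0], [1, 1, 0, 0])
        lo, hi = bootstrap_ci(s, "auroc", n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_reproducibility(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        s = ScoreLabelSet(scores, labels)
        ci1 = bootstrap_ci(s, "auprc", n_boot=300, seed=42)
        ci2 = bootstrap_ci(s, "auprc", n_boot=300, seed=42)
        assert ci1 == ci2


class TestComparisons:
    def _paired_sets(self, rng, better=1.5):
        n_pos, n_neg = 40, 60
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        signal = np.r_[rng.normal(better, 1, n_pos), rng.normal(0, 1, n_neg)]
        weak = 0.3 * signal + rng.normal(0, 1, labels.size)
        return ScoreLabelSet(signal, labels), ScoreLabelSet(weak, labels)

    def test_self_comparison_is_null(self, rng):
        s, _ = self._paired_sets(rng)
        res = compare_to_reference(s, s, metric="auroc", n_boot=200, seed=1)
        assert res.delta == 0.0
        assert res.ci_low == 0.0 and res.ci_high == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_sign_antisymmetry(self, rng):
        a, b = self._paired_sets(rng)
        r_ab = compare_to_reference(a, b, metric="auprc", n_boot=300, seed=9)
        r_ba = compare_to_reference(b, a, metric="auprc", n_boot=300, seed=9)
        assert r_ab.delta == pytest.approx(-r_ba.delta)

    def test_stronger_marker_wins_with_significance(self, rng):
        a, b = self._paired_sets(rng, better=2.0)
        res = compare_to_reference(a, b, metric="auroc", n_boot=300, seed=3)
        assert res.delta > 0
        assert res.ci_low > 0
        assert res.p_value is not None and res.p_value < 0.01

    def test_delong_requires_identical_labels(self, rng):
        a, _ = self._paired_sets(rng)
        other = ScoreLabelSet(a.scores, 1 - a.labels)
        with pytest.raises(ValueError):
            delong_auroc_test(a, other)

    def test_mismatched_subjects_rejected(self, rng):
        a, _ = self._paired_sets(rng)
        shorter = ScoreLabelSet(a.scores[:-1], a.labels[:-1])
        with pytest.raises(ValueError):
            compare_to_reference(a, shorter, metric="auprc", n_boot=10, seed=0)
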