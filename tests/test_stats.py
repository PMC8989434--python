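"""Evaluation statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from ctatrophy.stats import (
    agreement_stats,
    binary_metrics,
    delong_test,
    kappa,
    multiclass_metrics,
    roc_auc,
)


def brute_force_auc(scores, truth):
    pos = scores[truth]
    neg = scores[~truth]
    wins = np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :])
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_definitional_counts(self):
        truth = [True] * 10 + [False] * 10
        pred = [True] * 9 + [False] * 1 + [True] * 2 + [False] * 8
        bm = binary_metrics(pred, truth)
        assert bm.sensitivity == pytest.approx(0.9)
        assert bm.specificity == pytest.approx(0.8)
        assert bm.accuracy == pytest.approx(0.85)

    def test_perfect_prediction(self):
        truth = [True, False, True, False]
        bm = binary_metrics(truth, truth)
        assert (bm.sensitivity, bm.specificity, bm.accuracy, bm.f1) == (1, 1, 1, 1)

    def test_accuracy_matches_counting_oracle(self, rng):
        pred = rng.uniform(size=200) < 0.5
        truth = rng.uniform(size=200) < 0.5
        bm = binary_metrics(pred, truth)
        assert bm.accuracy == sum(p == t for p, t in zip(pred, truth)) / 200

    def test_single_class_truth_reports_undefined(self):
        bm = binary_metrics([True, False], [True, True])
        assert np.isnan(bm.specificity)
        assert any("specificity" in n for n in bm.notes)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([True], [True, False])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert ci[0] <= auc <= ci[1]

    def test_complete_ties(self):
        auc, _ = roc_auc([0.5] * 8, [0, 1] * 4)
        assert auc == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 500))
            truth = rng.uniform(size=n) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.normal(size=n) + truth, 1)  # coarse: many ties
            auc, _ = roc_auc(scores, truth)
            assert auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        truth = rng.uniform(size=50) < 0.5
        truth[:2] = [True, False]
        s = rng.normal(size=50) + truth
        a1, a2, p = delong_test(s, s, truth)
        assert a1 == a2
        assert p == 1.0

    def test_symmetric_in_arguments(self, rng):
        truth = rng.uniform(size=80) < 0.5
        truth[:2] = [True, False]
        a = rng.normal(size=80) + truth
        b = rng.normal(size=80) + 0.5 * truth
        _, _, p_ab = delong_test(a, b, truth)
        _, _, p_ba = delong_test(b, a, truth)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1], [1, 0])


class TestKappa:
    @pytest.mark.parametrize("weighting", ["none", "linear", "quadratic"])
    def test_perfect_agreement(self, weighting):
        labels = [0, 1, 2, 1, 0, 2]
        assert kappa(labels, labels, weighting) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40))
    def test_two_category_linear_equals_unweighted(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert kappa(a, b, "linear", categories=[0, 1]) == pytest.approx(
            kappa(a, b, "none", categories=[0, 1]), abs=1e-12
        )

    def test_fixed_confusion_table_matches_hand_expansion(self):
        # raters: 3x3 confusion [[4,1,0],[1,5,1],[0,2,6]] (rows = rater a)
        table = np.array([[4, 1, 0], [1, 5, 1], [0, 2, 6]], dtype=float)
        a, b = [], []
        for i in range(3):
            for j in range(3):
                a += [i] * int(table[i, j])
                b += [j] * int(table[i, j])
        n = table.sum()
        obs = table / n
        expected = np.outer(obs.sum(1), obs.sum(0))
        ii, jj = np.meshgrid(range(3), range(3), indexing="ij")
        w = np.abs(ii - jj) / 2.0
        hand = 1 - (w * obs).sum() / (w * expected).sum()
        assert kappa(a, b, "linear") == pytest.approx(hand, abs=1e-12)

    def test_matches_sklearn(self, rng):
        for weighting, sk in (("none", None), ("linear", "linear"), ("quadratic", "quadratic")):
            a = rng.integers(0, 3, 60)
            b = rng.integers(0, 3, 60)
            ours = kappa(a.tolist(), b.tolist(), weighting, categories=[0, 1, 2])
            theirs = cohen_kappa_score(a, b, weights=sk, labels=[0, 1, 2])
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kappa([], [], "none")


class TestAgreement:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ag = agreement_stats(x, x)
        assert ag.pearson_r == pytest.approx(1.0)
        assert ag.paired_t == 0.0
        assert ag.t_p_value == 1.0

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        ag = agreement_stats(x, -x)
        assert ag.pearson_r == pytest.approx(-1.0)

    def test_r_matches_direct_formula(self, rng):
        x = rng.normal(size=1000)
        y = 0.5 * x + rng.normal(size=1000)
        ag = agreement_stats(x, y)
        direct = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert ag.pearson_r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_reported(self):
        ag = agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(ag.pearson_r)
        assert any("zero variance" in n for n in ag.notes)


class TestMulticlass:
    def test_perfect(self):
        y = ["no_atrophy", "mild", "severe"] * 3
        mm = multiclass_metrics(y, y)
        assert (mm.accuracy, mm.average_f1, mm.weighted_kappa) == (1, 1, 1)

    def test_toy_confusion_accuracy(self):
        truth = ["no_atrophy"] * 5 + ["mild"] * 8 + ["severe"] * 5
        pred = ["no_atrophy"] * 5 + ["mild"] * 5 + ["no_atrophy"] * 3 + ["severe"] * 5
        mm = multiclass_metrics(pred, truth)
        assert mm.accuracy == pytest.approx(15 / 18)

    def test_macro_f1_equals_mean_of_one_vs_rest(self, rng):
        classes = ("no_atrophy", "mild", "severe")
        truth = [classes[i] for i in rng.integers(0, 3, 90)]
        pred = [classes[i] for i in rng.integers(0, 3, 90)]
        mm = multiclass_metrics(pred, truth)
        f1s = []
        for c in classes:
            bm = binary_metrics([p == c for p in pred], [t == c for t in truth])
            f1s.append(0.0 if np.isnan(bm.f1) else bm.f1)
        assert mm.average_f1 == pytest.approx(np.mean(f1s), abs=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            multiclass_metrics(["bad"], ["mild"])
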