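"""Metrics and the cross-validation harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petcam.evaluation import (
    ConfusionCounts,
    PipelineConfig,
    UndefinedMetricError,
    auc,
    confusion_from_predictions,
    dice,
    evaluate_pipeline,
    iou,
    make_folds,
    sens_spec_acc,
)
from petcam.losses import TrainConfig
from petcam.net import ClassifierConfig
from petcam.outcome import OutcomeConfig

RNG = np.random.default_rng(61)


class TestOverlapMetrics:
    def test_identical_masks_score_one(self):
        m = RNG.random((5, 5, 5)) > 0.5
        assert dice(m, m) == 1.0 and iou(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_counting_oracle_two_and_two_overlap_one(self):
        a = np.zeros(6, bool)
        b = np.zeros(6, bool)
        a[[0, 1]] = True
        b[[1, 2]] = True
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_empty_vs_empty_convention(self):
        e = np.zeros((3, 3), bool)
        assert dice(e, e) == 1.0 and iou(e, e) == 1.0
        assert dice(e, ~e) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @given(st.integers(0, 2**36 - 1))
    @settings(max_examples=50, deadline=None)
    def test_iou_equals_dice_over_two_minus_dice(self, bits):
        """Algebraic identity iou = dice / (2 - dice) for any mask pair."""
        a = np.array([(bits >> i) & 1 for i in range(18)], bool).reshape(3, 6)
        b = np.array([(bits >> i) & 1 for i in range(18, 36)], bool).reshape(3, 6)
        d, j = dice(a, b), iou(a, b)
        assert abs(j - d / (2 - d)) < 1e-12


class TestConfusionMetrics:
    def test_reference_contingency(self):
        sens, spec, acc = sens_spec_acc(ConfusionCounts(tp=8, fn=2, tn=6, fp=4))
        assert (sens, spec, acc) == (0.8, 0.6, 0.7)

    def test_perfect_classifier(self):
        assert sens_spec_acc(ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_all_positive_predictor_on_balanced_set(self):
        sens, spec, acc = sens_spec_acc(ConfusionCounts(tp=5, fn=0, tn=0, fp=5))
        assert (sens, spec, acc) == (1.0, 0.0, 0.5)

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            sens_spec_acc(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))

    def test_confusion_from_predictions_counts(self):
        c = confusion_from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
        assert c.total == 4


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_four_point_pair_counting_oracle(self):
        labels = np.array([0, 1, 0, 1])
        scores = np.array([0.3, 0.2, 0.6, 0.9])
        wins = ties = 0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                wins += scores[i] > scores[j]
                ties += scores[i] == scores[j]
        expected = (wins + 0.5 * ties) / 4
        assert auc(labels, scores) == pytest.approx(expected)

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        labels = RNG.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = np.round(RNG.random(30), 1)  # ties included
        assert auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auc([1, 1], [0.2, 0.4])


class TestMakeFolds:
    def test_paper_scale_fold_sizes_disjoint_and_covering(self):
        labels = np.array([0] * 97 + [1] * 98)
        ids = [f"p{i}" for i in range(195)]
        folds = make_folds(ids, labels, k=5, seed=0)
        seen = []
        for f in folds:
            assert 39 <= len(f.test) <= 40
            assert not (set(f.train) & set(f.val))
            assert not (set(f.train) | set(f.val)) & set(f.test)
            seen.extend(f.test)
        assert sorted(seen) == sorted(ids)

    def test_same_seed_reproduces_folds(self):
        labels = RNG.integers(0, 2, 40)
        ids = list(range(40))
        a = make_folds(ids, labels, k=4, seed=3)
        b = make_folds(ids, labels, k=4, seed=3)
        assert [(f.train, f.val, f.test) for f in a] == [
            (f.train, f.val, f.test) for f in b
        ]

    def test_stratification_within_one_patient(self):
        labels = np.array([0] * 50 + [1] * 50)
        ids = list(range(100))
        by_id = dict(zip(ids, labels))
        for f in make_folds(ids, labels, k=5, seed=1):
            n1 = sum(by_id[i] for i in f.test)
            assert abs(n1 - len(f.test) / 2) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            make_folds(list(range(10)), [0] * 9 + [1], k=5, seed=0)


class TestEvaluatePipeline:
    @pytest.fixture(scope="class")
    def report(self, tiny_cohort):
        config = PipelineConfig(
            k=2,
            seed=0,
            train=TrainConfig(alpha=1.0, lr=1e-3, epochs=3, seed=0),
            classifier=ClassifierConfig.small(input_shape=(48, 24), seed=0),
            outcome=OutcomeConfig(crop_shape=(16, 16, 16), channels=(2, 4),
                                  dense_width=8, epochs=3, seed=0),
        )
        return evaluate_pipeline(tiny_cohort, config), config, tiny_cohort

    def test_aggregate_mean_equals_mean_of_folds(self, report):
        rep, _, _ = report
        for key, value in rep["mean"].items():
            vals = [f[key] for f in rep["folds"] if key in f]
            assert value == pytest.approx(np.mean(vals))

    def test_report_reproducible_under_fixed_seed(self, report):
        rep, config, cohort = report
        again = evaluate_pipeline(cohort, config)
        assert again == rep

    def test_report_contains_segmentation_and_outcome_metrics(self, report):
        rep, _, _ = report
        assert {"dice", "iou", "class_accuracy"} <= set(rep["mean"])
        assert all(0 <= f["dice"] <= 1 for f in rep["folds"])
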