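"""Multitask objective: closed forms, invariants, training contracts."""

import numpy as np
import pytest

from petcam._nn import Adam
from petcam.losses import (
    LossReport,
    MipDataset,
    TrainConfig,
    _flatten_views,
    classification_loss,
    distance_loss,
    global_loss,
    train_classifier,
    train_step,
)
from petcam.net import ClassifierConfig, MipClassifier

RNG = np.random.default_rng(31)


class TestClassificationLoss:
    def test_perfect_prediction_is_nearly_zero(self):
        assert classification_loss([1.0], [1.0 - 1e-7]) < 1e-6

    def test_half_probability_is_ln2(self):
        assert classification_loss([1.0], [0.5]) == pytest.approx(np.log(2))

    def test_matches_exhaustive_sum(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        p = np.array([0.8, 0.3, 0.6, 0.9])
        expected = -np.mean(
            [np.log(0.8), np.log(0.7), np.log(0.6), np.log(0.1)]
        )
        assert classification_loss(y, p) == pytest.approx(expected)

    def test_saturated_probabilities_are_clamped(self):
        assert np.isfinite(classification_loss([1.0, 0.0], [0.0, 1.0]))


class TestDistanceLoss:
    def test_all_mass_at_prior_point_gives_zero(self):
        h = np.zeros((9, 9))
        h[4, 4] = 1.0
        assert distance_loss(h, (4, 4)) == 0.0

    def test_point_mass_returns_euclidean_distance(self):
        h = np.zeros((9, 9))
        h[4, 7] = 0.6
        assert distance_loss(h, (4, 2)) == pytest.approx(5.0)

    def test_uniform_3x3_closed_form(self):
        h = np.ones((3, 3))
        expected = (0 + 4 * 1 + 4 * np.sqrt(2)) / 9
        assert distance_loss(h, (1, 1)) == pytest.approx(expected)

    def test_zero_map_contributes_zero(self):
        assert distance_loss(np.zeros((5, 5)), (2, 2)) == 0.0

    def test_out_of_bounds_prior_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            distance_loss(np.ones((5, 5)), (5, 0))

    def test_translation_invariance(self):
        h = np.zeros((12, 12))
        h[2:5, 3:6] = RNG.random((3, 3))
        a = distance_loss(h, (3, 4))
        shifted = np.roll(np.roll(h, 4, axis=0), 3, axis=1)
        b = distance_loss(shifted, (7, 7))
        assert a == pytest.approx(b)

    def test_moving_mass_farther_strictly_increases_loss(self):
        near, far = np.zeros((11, 11)), np.zeros((11, 11))
        near[5, 6] = far[5, 9] = 1.0
        base = np.zeros((11, 11))
        base[5, 5] = 1.0
        assert distance_loss(base + near, (5, 5)) < distance_loss(base + far, (5, 5))


class TestGlobalLoss:
    def test_alpha_zero_is_classification_only(self):
        assert global_loss(0.7, 123.0, alpha=0.0) == 0.7

    def test_weighted_sum(self):
        assert global_loss(0.5, 2.0, alpha=1.0) == 2.5

    def test_alpha_one_is_default(self):
        assert global_loss(0.5, 2.0) == 2.5

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            global_loss(1.0, 1.0, alpha=-0.1)

    def test_report_invariant_exact(self):
        rep = LossReport(l_class=0.25, l_distance=1.5, alpha=0.5)
        assert rep.loss_glob == 0.25 + 0.5 * 1.5


@pytest.fixture(scope="module")
def tiny_dataset(tiny_cohort):
    return MipDataset.from_patients(tiny_cohort)


def _small_config(seed=0):
    return ClassifierConfig.small(input_shape=(48, 24), seed=seed)


class TestTrainStep:
    def test_loss_glob_identity_every_step(self, tiny_dataset):
        model = MipClassifier(_small_config())
        opt = Adam(model.parameters(), lr=1e-3)
        mips, labels, priors = _flatten_views(
            tiny_dataset.x, tiny_dataset.labels, tiny_dataset.priors
        )
        for _ in range(5):
            rep = train_step(model, opt, mips, labels, priors, alpha=1.0)
            assert rep.loss_glob == rep.l_class + rep.alpha * rep.l_distance
            assert rep.l_class >= 0 and rep.l_distance >= 0

    def test_alpha_zero_reproduces_pure_classifier_bitwise(self, tiny_dataset):
        """Training with alpha=0 must equal a classification-only loop
        parameter-for-parameter under a shared seed."""
        mips, labels, priors = _flatten_views(
            tiny_dataset.x, tiny_dataset.labels, tiny_dataset.priors
        )
        model_a = MipClassifier(_small_config(seed=5))
        opt_a = Adam(model_a.parameters(), lr=1e-3)
        for _ in range(3):
            train_step(model_a, opt_a, mips, labels, priors, alpha=0.0)

        model_b = MipClassifier(_small_config(seed=5))
        opt_b = Adam(model_b.parameters(), lr=1e-3)
        for _ in range(3):
            model_b.zero_grad()
            pred = model_b.forward(mips, train=True)
            dlogit = (pred.y_hat - labels) / mips.shape[0]
            grad_f = model_b.backward_from_head(dlogit)
            model_b.backward_conv(grad_f)
            opt_b.step()

        for (la, na), (lb, nb) in zip(model_a.parameters(), model_b.parameters()):
            np.testing.assert_array_equal(la.params[na], lb.params[nb])

    def test_loss_decreases_over_50_steps_on_toy_cohort(self, tiny_dataset):
        model = MipClassifier(_small_config(seed=1))
        opt = Adam(model.parameters(), lr=1e-3)
        mips, labels, priors = _flatten_views(
            tiny_dataset.x, tiny_dataset.labels, tiny_dataset.priors
        )
        reports = [
            train_step(model, opt, mips, labels, priors, alpha=1.0)
            for _ in range(50)
        ]
        first = np.mean([r.loss_glob for r in reports[:5]])
        last = np.mean([r.loss_glob for r in reports[-5:]])
        assert last < first

    def test_negative_alpha_rejected(self, tiny_dataset):
        model = MipClassifier(_small_config())
        opt = Adam(model.parameters(), lr=1e-3)
        mips, labels, priors = _flatten_views(
            tiny_dataset.x, tiny_dataset.labels, tiny_dataset.priors
        )
        with pytest.raises(ValueError, match="alpha"):
            train_step(model, opt, mips, labels, priors, alpha=-1.0)


def test_train_classifier_is_seeded_deterministic(tiny_dataset):
    cfg = TrainConfig(alpha=1.0, lr=1e-3, epochs=2, seed=9)
    m1, h1 = train_classifier(tiny_dataset, cfg, classifier_config=_small_config(9))
    m2, h2 = train_classifier(tiny_dataset, cfg, classifier_config=_small_config(9))
    assert h1 == h2
    for (la, na), (lb, nb) in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(la.params[na], lb.params[nb])
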