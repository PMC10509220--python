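"""Softmax/cross-entropy contracts, the training loop, and LR scheduling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynaquery import (
    ClassifierModel,
    LossHistory,
    OptimizerConfig,
    cross_entropy,
    softmax,
    train_epoch,
    update_learning_rate,
)
from dynaquery.nnet import Dense, Parameter, SGDNesterov


class TestSoftmax:
    @pytest.mark.parametrize(
        "logits, expected",
        [
            ((0.0, 0.0), (0.5, 0.5)),
            ((3.7, 3.7), (0.5, 0.5)),
            ((math.log(3), 0.0), (0.75, 0.25)),
        ],
    )
    def test_known_values(self, logits, expected):
        np.testing.assert_allclose(softmax(np.array(logits)), expected, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=5), st.floats(-20, 20))
    def test_normalization_and_shift_invariance(self, logits, shift):
        z = np.array(logits)
        p = softmax(z)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(softmax(z + shift), p, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.nan, 0.0]))


class TestCrossEntropy:
    @pytest.mark.parametrize(
        "probs, truth, expected",
        [
            ((1.0, 0.0), (1, 0), 0.0),
            ((0.5, 0.5), (0, 1), math.log(2)),
            ((0.25, 0.75), (0, 1), -math.log(0.75)),
        ],
    )
    def test_known_values(self, probs, truth, expected):
        assert cross_entropy(np.array(probs), np.array(truth)) == pytest.approx(expected)

    def test_zero_probability_clamped(self):
        loss = cross_entropy(np.array([0.0, 1.0]), np.array([1, 0]))
        assert math.isfinite(loss)
        assert loss == pytest.approx(-math.log(1e-12))

    def test_monotone_in_true_class_logit(self):
        # raising the true-class logit (others fixed) lowers the loss
        truth = np.array([1, 0])
        losses = [
            cross_entropy(softmax(np.array([z, 0.0])), truth) for z in np.linspace(-3, 3, 13)
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))


class TestOptimizer:
    def test_weight_decay_shrinks_params_without_data_gradient(self):
        rng = np.random.default_rng(0)
        p = Parameter(rng.normal(size=(4, 3)).astype(np.float32))
        opt = SGDNesterov([p], lr=1e-2, momentum=0.95, weight_decay=1e-2)
        norms = [np.linalg.norm(p.value)]
        for _ in range(10):
            opt.zero_grad()  # data gradient identically zero
            opt.step()
            norms.append(np.linalg.norm(p.value))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            SGDNesterov([], lr=-1.0)
        with pytest.raises(ValueError):
            OptimizerConfig(momentum=1.0)


def _toy_samples(n=8, seed=0):
    """Linearly separable toy problem: metadata carries the class."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        cls = i % 2
        img = rng.uniform(-0.1, 0.1, (160, 200)).astype(np.float32)
        meta = np.full(4, 0.9 if cls else 0.1) + rng.normal(0, 0.01, 4)
        samples.append((img, meta, cls))
    return samples


class TestTrainEpoch:
    def test_empty_pool_rejected(self):
        model = ClassifierModel(4, seed=0)
        opt = SGDNesterov(model.params(), lr=1e-2)
        with pytest.raises(ValueError):
            train_epoch(model, [], opt, OptimizerConfig(), np.random.default_rng(0))

    def test_zero_lr_freezes_loss_without_augmentation(self):
        model = ClassifierModel(4, seed=0)
        opt = SGDNesterov(model.params(), lr=0.0, weight_decay=0.0)
        samples = _toy_samples()
        rng = np.random.default_rng(0)
        losses = [
            train_epoch(model, samples, opt, OptimizerConfig(), rng, augmentation=None)
            for _ in range(3)
        ]
        assert losses[0] == pytest.approx(losses[1], rel=1e-6)
        assert losses[1] == pytest.approx(losses[2], rel=1e-6)

    def test_separable_toy_problem_converges(self):
        model = ClassifierModel(4, seed=0)
        opt = SGDNesterov(model.params(), lr=1e-2, momentum=0.95, weight_decay=1e-2)
        samples = _toy_samples(n=12)
        rng = np.random.default_rng(1)
        losses = [
            train_epoch(model, samples, opt, OptimizerConfig(), rng, augmentation=None)
            for _ in range(60)
        ]
        assert np.mean(losses[-5:]) < 0.2 * losses[0]

    def test_single_sample_updates_parameters(self):
        model = ClassifierModel(4, seed=0)
        before = [p.value.copy() for p in model.params()]
        opt = SGDNesterov(model.params(), lr=1e-2)
        train_epoch(model, _toy_samples(n=1), opt, OptimizerConfig(), np.random.default_rng(0))
        assert any(not np.array_equal(b, p.value) for b, p in zip(before, model.params()))


class TestLearningRateSchedule:
    CFG = OptimizerConfig()

    def test_strictly_decreasing_loss_keeps_lr(self):
        hist = LossHistory(per_epoch_loss=list(np.linspace(1.0, 0.1, 50)))
        assert update_learning_rate(1e-2, hist, self.CFG) == 1e-2

    def test_twenty_epoch_stall_fires_once(self):
        losses = list(np.linspace(1.0, 0.1, 10)) + [0.1] * 20
        fired = []
        lr = 1e-2
        for t in range(1, len(losses) + 1):
            hist = LossHistory(per_epoch_loss=losses[:t])
            new = update_learning_rate(lr, hist, self.CFG)
            if new != lr:
                fired.append(t)
            lr = new
        assert fired == [30]
        assert lr == pytest.approx(1e-2 * 0.9)

    def test_two_stalls_compound(self):
        losses = list(np.linspace(1.0, 0.1, 10)) + [0.1] * 40
        lr = 1e-2
        for t in range(1, len(losses) + 1):
            lr = update_learning_rate(lr, LossHistory(per_epoch_loss=losses[:t]), self.CFG)
        assert lr == pytest.approx(1e-2 * 0.81)

    def test_start_epoch_scopes_replay(self):
        # a deep pre-query minimum must not count once the replay is scoped
        losses = [1e-6] * 5 + list(np.linspace(0.5, 0.05, 30))
        hist = LossHistory(per_epoch_loss=losses, query_epochs=[0, 5])
        assert update_learning_rate(1e-2, hist, self.CFG, start_epoch=5) == 1e-2


class TestModelContract:
    def test_logit_shape_and_probability_vector(self):
        model = ClassifierModel(6, seed=3)
        imgs = np.random.default_rng(0).uniform(-1, 1, (5, 160, 200)).astype(np.float32)
        metas = np.random.default_rng(1).uniform(0, 1, (5, 6))
        logits = model.forward(imgs, metas)
        assert logits.shape == (5, 2)
        probs = model.predict_proba(imgs, metas)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        model = ClassifierModel(6, seed=3)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = ClassifierModel.load(path)
        imgs = np.random.default_rng(0).uniform(-1, 1, (2, 160, 200)).astype(np.float32)
        metas = np.zeros((2, 6))
        np.testing.assert_array_equal(model.forward(imgs, metas), clone.forward(imgs, metas))
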