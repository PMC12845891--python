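"""Dice loss closed forms, oversampling weights, training-loop contracts."""

import numpy as np
import pytest

from ecgseg import PAC, PVC, LabelMask, ModelConfig, UNet1d, dice_loss
from ecgseg.records import BeatAnnotation, NORMAL
from ecgseg.synthetic import RhythmSpec, default_training_mix, generate_dataset
from ecgseg.training import TrainConfig, make_sampler, one_cycle_lr, train

TINY = ModelConfig(base_filters=4, blocks_per_stage=(1, 1, 1, 1))


class TestDiceLoss:
    def test_perfect_prediction_is_exactly_zero(self, rng):
        labels = rng.integers(0, 4, size=200)
        mask = LabelMask(labels=labels, fs=125.0)
        pred = np.eye(4)[labels]
        assert dice_loss(pred, mask) == 0.0

    def test_two_class_uniform_closed_form(self):
        # target all class 1, prediction uniform 0.5 -> loss -> 2/3
        n = 10_000
        pred = np.full((n, 2), 0.5)
        target = np.ones(n, dtype=int)
        assert abs(dice_loss(pred, target) - 2.0 / 3.0) < 1e-3

    def test_empty_classes_use_epsilon_convention(self):
        # both all-background: the three empty classes contribute eps/eps = 1
        n = 500
        target = np.zeros(n, dtype=int)
        pred = np.eye(4)[target]
        assert dice_loss(pred, target) == 0.0

    def test_strictly_decreases_toward_target(self, rng):
        labels = rng.integers(0, 4, size=300)
        onehot = np.eye(4)[labels]
        uniform = np.full_like(onehot, 0.25)
        losses = [
            dice_loss((1 - a) * uniform + a * onehot, labels)
            for a in np.linspace(0, 1, 6)
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert 0.0 <= losses[0] <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((10, 4), 0.25), np.zeros(9, dtype=int))


class TestSampler:
    def _dataset(self, label_sets):
        out = []
        for labels in label_sets:
            anns = [BeatAnnotation(10 * (i + 1), c) for i, c in enumerate(labels)]
            out.append((None, anns))
        return out

    def test_unit_factors_give_uniform_weights(self):
        data = self._dataset([[NORMAL]] * 6)
        w = make_sampler(data, {PVC: 1.0, PAC: 1.0})
        assert np.allclose(w, 1 / 6)

    def test_pvc_factor_weighting(self):
        data = self._dataset([[NORMAL]] * 9 + [[NORMAL, PVC]])
        w = make_sampler(data, {PVC: 5.0, PAC: 1.0})
        assert w[-1] == pytest.approx(5 / 14)
        assert np.allclose(w[:-1], 1 / 14)

    def test_mixed_segment_takes_max_factor(self):
        data = self._dataset([[NORMAL], [PVC, PAC]])
        w = make_sampler(data, {PVC: 3.0, PAC: 7.0})
        assert w[1] / w[0] == pytest.approx(7.0)

    def test_no_zero_weights_and_validation(self):
        data = self._dataset([[NORMAL], [PVC]])
        assert (make_sampler(data, {PVC: 100.0}) > 0).all()
        with pytest.raises(ValueError):
            make_sampler([], {PVC: 2.0})
        with pytest.raises(ValueError):
            make_sampler(data, {PVC: 0.5})


def test_one_cycle_schedule_shape():
    lrs = [one_cycle_lr(s, 100, 1e-3) for s in range(100)]
    peak = int(np.argmax(lrs))
    assert lrs[peak] == pytest.approx(1e-3, rel=1e-6)
    assert lrs[0] < lrs[peak] and lrs[-1] < lrs[0]


@pytest.fixture(scope="module")
def records():
    data, _ = generate_dataset(24, default_training_mix(), 20.0, 125.0, seed=7)
    return data


class TestTrainLoop:
    def test_smoke_single_epoch(self, records):
        model = UNet1d(TINY, seed=0)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        model, hist = train(model, records[:10], records[20:], cfg)
        assert len(hist) == 1
        assert np.isfinite(hist[0]["loss"])
        assert "PVC_F1" in hist[0]

    def test_loss_decreases_over_epochs(self, records):
        model = UNet1d(TINY, seed=0)
        cfg = TrainConfig(epochs=10, batch_size=4, lr_max=3e-3, seed=0,
                          early_stop_patience=20, augment=None)
        model, hist = train(model, records[:20], records[20:], cfg)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_frozen_model_early_stops_after_two_epochs(self, records):
        model = UNet1d(TINY, seed=0)
        cfg = TrainConfig(epochs=10, batch_size=8, lr_init=0.0, lr_max=0.0,
                          early_stop_patience=1, seed=0, augment=None)
        model, hist = train(model, records[:8], records[20:], cfg)
        assert len(hist) == 2

    def test_history_is_reproducible_for_fixed_seed(self, records):
        runs = []
        for _ in range(2):
            model = UNet1d(TINY, seed=3)
            cfg = TrainConfig(epochs=1, batch_size=8, seed=3)
            _m, hist = train(model, records[:8], records[20:], cfg)
            runs.append(hist[0]["loss"])
        assert runs[0] == runs[1]

    def test_validation_without_annotations_rejected(self, records):
        model = UNet1d(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, records[:4], [(records[0][0], [])],
                  TrainConfig(epochs=1))
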