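"""Training strategy: splits, preprocessing, optimization, diagnostics."""

import numpy as np
import pytest

import octseg as o
from octseg.trainer import TrainingHistory

from conftest import noisefree_spec


class TestSplit:
    def test_sixty_items_give_48_12_convention(self):
        s = o.split_dataset(range(60), test_fraction=0.20,
                            validation_fraction=0.2, seed=0)
        assert len(s.test_items) == 12
        assert len(s.train_items) + len(s.val_items) == 48

    def test_ten_items_give_6_2_2(self):
        s = o.split_dataset(range(10), test_fraction=0.20,
                            validation_fraction=0.25, seed=1)
        assert (len(s.train_items), len(s.val_items), len(s.test_items)) == (6, 2, 2)
        all_items = s.train_items + s.val_items + s.test_items
        assert sorted(all_items) == list(range(10))

    def test_same_seed_same_partition(self):
        a = o.split_dataset(range(20), seed=5)
        b = o.split_dataset(range(20), seed=5)
        assert a == b

    def test_no_leakage_across_seeds(self):
        for seed in range(25):
            s = o.split_dataset(range(60), seed=seed)
            assert not set(s.test_items) & set(s.train_items)
            assert not set(s.test_items) & set(s.val_items)
            assert not set(s.train_items) & set(s.val_items)

    def test_too_few_items_suggests_minimum(self):
        with pytest.raises(ValueError, match="at least 5"):
            o.split_dataset(range(3))


class TestPreparePair:
    def test_mask_stays_binary_after_downscale(self):
        img = np.random.default_rng(0).random((464, 1356))
        mask = np.zeros((464, 1356), np.uint8)
        mask[100:160] = 1
        _, m = o.prepare_pair(img, mask, (256, 256))
        assert set(np.unique(m)) <= {0, 1}

    def test_same_size_is_identity_on_mask(self):
        img = np.random.default_rng(1).random((32, 32))
        mask = (np.random.default_rng(2).random((32, 32)) < 0.5).astype(np.uint8)
        _, m = o.prepare_pair(img, mask, (32, 32))
        assert np.array_equal(m, mask)

    def test_band_thickness_scales_with_resize(self):
        mask = np.zeros((464, 600), np.uint8)
        mask[200:220] = 1  # 20-px band
        img = np.random.default_rng(3).random((464, 600))
        _, m = o.prepare_pair(img, mask, (256, 256))
        thickness = m.sum(axis=0)
        expected = 20 * 256 / 464
        assert np.all(np.abs(thickness - expected) <= 1.0)

    def test_image_scaled_to_unit_interval(self):
        img = np.random.default_rng(4).random((32, 32)) * 255
        mask = np.zeros((32, 32), np.uint8)
        mask[4:8] = 1
        out, _ = o.prepare_pair(img, mask, (32, 32))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_binary_mask_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError, match="binary"):
            o.prepare_pair(img, np.full((8, 8), 7), (8, 8))


def make_micro_problem(n=6, size=32):
    """Tiny learnable dataset: noise-free bands at 32x32."""
    specs = [noisefree_spec(seed=s, height=size, width=size,
                            surface_depth_mean=6.0,
                            surface_roughness_amplitude=2.0,
                            epidermis_thickness_mean=8.0,
                            epidermis_thickness_amplitude=2.0,
                            hyperkeratosis_extra_thickness=3.0)
             for s in range(n)]
    return [(p.image, p.mask) for p in map(o.generate_phantom, specs)]


class TestTrain:
    def test_single_epoch_bookkeeping(self):
        data = make_micro_problem()
        split = o.SplitResult(train_items=[0, 1, 2, 3], val_items=[4],
                              test_items=[5])
        model = o.build_model(o.ModelConfig(input_height=32, input_width=32,
                                            base_filters=2))
        cfg = o.TrainConfig(image_size=(32, 32), epochs=1)
        h = o.train(model, data, split, cfg)
        assert h.stopped_epoch == 1
        for series in (h.train_loss, h.train_accuracy, h.val_loss,
                       h.val_accuracy, h.lr_schedule):
            assert len(series) == 1

    def test_loss_decreases_on_learnable_problem(self):
        data = make_micro_problem()
        split = o.SplitResult(train_items=[0, 1, 2, 3], val_items=[4],
                              test_items=[5])
        model = o.build_model(o.ModelConfig(input_height=32, input_width=32,
                                            base_filters=4), seed=0)
        cfg = o.TrainConfig(image_size=(32, 32), epochs=12, init_seed=0)
        h = o.train(model, data, split, cfg)
        assert h.train_loss[-1] < h.train_loss[0]
        assert all(a <= b + 1e-12 for a, b in
                   zip(h.lr_schedule[1:], h.lr_schedule[:-1]))

    def test_effectively_frozen_weights_stop_early(self):
        data = make_micro_problem()
        split = o.SplitResult(train_items=[0, 1], val_items=[2],
                              test_items=[3])
        model = o.build_model(o.ModelConfig(input_height=32, input_width=32,
                                            base_filters=2), seed=1)
        cfg = o.TrainConfig(image_size=(32, 32), epochs=20,
                            learning_rate=1e-30, early_stop_patience=2)
        h = o.train(model, data, split, cfg)
        assert h.stopped_epoch <= 3

    def test_empty_partition_rejected(self):
        data = make_micro_problem()
        model = o.build_model(o.ModelConfig(input_height=32, input_width=32,
                                            base_filters=2))
        cfg = o.TrainConfig(image_size=(32, 32), epochs=1)
        with pytest.raises(ValueError, match="non-empty"):
            o.train(model, data,
                    o.SplitResult(train_items=[], val_items=[0],
                                  test_items=[1]), cfg)

    def test_model_size_must_match_config(self):
        data = make_micro_problem()
        model = o.build_model(o.ModelConfig(input_height=16, input_width=16,
                                            base_filters=2))
        cfg = o.TrainConfig(image_size=(32, 32), epochs=1)
        split = o.SplitResult(train_items=[0], val_items=[1], test_items=[2])
        with pytest.raises(ValueError, match="does not match"):
            o.train(model, data, split, cfg)


class TestLearnability:
    def test_noise_free_validation_accuracy(self, noisefree_run):
        """On noise-free phantoms the pipeline exceeds 95% pixel accuracy."""
        _, _, _, history = noisefree_run
        assert max(history.val_accuracy) > 0.95


def history_from(train_loss, val_loss):
    n = len(train_loss)
    return TrainingHistory(train_loss=list(train_loss),
                           train_accuracy=[0.9] * n,
                           val_loss=list(val_loss),
                           val_accuracy=[0.9] * n,
                           lr_schedule=[1e-3] * n)


class TestDetectOverfit:
    def test_equal_curves_not_flagged(self):
        h = history_from([0.5] * 6, [0.5] * 6)
        flag, _ = o.detect_overfit(h, gap_margin=0.1, trend_window=5)
        assert not flag

    def test_diverging_curves_flagged(self):
        train = np.linspace(1.0, 0.1, 10)
        val = np.linspace(0.5, 0.9, 10)
        flag, text = o.detect_overfit(history_from(train, val),
                                      gap_margin=0.1, trend_window=5)
        assert flag and "OVERFIT" in text

    def test_parallel_descent_with_small_gap_not_flagged(self):
        train = np.linspace(1.0, 0.2, 10)
        val = train + 0.05
        flag, _ = o.detect_overfit(history_from(train, val),
                                   gap_margin=0.1, trend_window=5)
        assert not flag

    def test_short_history_raises(self):
        h = history_from([0.5] * 3, [0.5] * 3)
        with pytest.raises(ValueError, match="shorter"):
            o.detect_overfit(h, trend_window=5)
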