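import numpy as np
import pytest

import deepfat.model as model_mod
from deepfat import _nn
from deepfat.evaluate import dice
from deepfat.model import (
    OracleSegmenter,
    TinyUNet,
    TrainingConfig,
    TrainingLog,
    make_dataset,
    segment_volume,
    soft_dice_loss,
    train_segmenter,
)
from deepfat.phantom import PhantomSpec, generate_phantom
from deepfat.preprocess import Slab, bisect_plan, sequential_plan


class TestSoftDiceLoss:
    def test_perfect_overlap(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(np.float32)
        assert soft_dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_perfect_anti_overlap(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(np.float32)
        assert soft_dice_loss(1.0 - t, t) == pytest.approx(1.0, abs=1e-5)

    def test_hand_evaluation(self):
        """Uniform 0.5 prediction on a 4-pixel grid with two true pixels:
        1 - 2*1/(2+2) = 0.5."""
        pred = np.full((2, 2), 0.5, np.float32)
        truth = np.array([[1, 1], [0, 0]], np.float32)
        assert soft_dice_loss(pred, truth) == pytest.approx(0.5, abs=1e-6)

    def test_complement_of_binary_dice(self, rng):
        """For binary predictions, soft loss + Dice score = 1 (eps-bounded)."""
        p = (rng.random((10, 10)) > 0.5).astype(np.float32)
        t = (rng.random((10, 10)) > 0.5).astype(np.float32)
        assert soft_dice_loss(p, t) + dice(p, t) == pytest.approx(1.0, abs=1e-4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.full((2, 2), 1.5), np.zeros((2, 2)))


class TestConvOracle:
    def test_conv_matches_scipy_correlation(self, rng):
        """The im2col convolution agrees with scipy's correlate2d."""
        from scipy.signal import correlate2d

        x = rng.random((2, 6, 6, 3)).astype(np.float32)
        w = rng.random((27, 4)).astype(np.float32)
        b = rng.random(4).astype(np.float32)
        y, _ = _nn.conv2d_forward(x, w, b)
        w4 = w.reshape(3, 3, 3, 4)
        for n in (0, 1):
            for f in range(4):
                ref = sum(
                    correlate2d(np.pad(x[n, :, :, c], 1), w4[:, :, c, f], mode="valid")
                    for c in range(3)
                ) + b[f]
                assert np.allclose(y[n, :, :, f], ref, atol=1e-4)


class TestEarlyStopping:
    def _tiny_setup(self):
        p = generate_phantom(
            PhantomSpec(shape_xy=16, n_heart_slices=4, n_pad_slices=0,
                        r_max_mm=4.0, eat_min_radius_mm=99.0,
                        paracardial_mm=0.7, wall_mm=0.7),
            seed=0,
        )
        data = make_dataset([(p.ct, p.extent, p.sac)])
        return TinyUNet(seed=0, channels=(2, 2, 2, 2, 2)), data

    def test_scripted_plateau_stops_with_tolerance(self, monkeypatch):
        """A validation-Dice sequence changing by < 1e-5 stops training
        after the second epoch."""
        scripted = iter([0.80, 0.80000001, 0.9, 0.95])
        monkeypatch.setattr(
            model_mod, "_mean_slice_dice", lambda m, v: next(scripted)
        )
        model, data = self._tiny_setup()
        _, log = train_segmenter(
            model, data, data, TrainingConfig(max_epochs=10, seed=0), augment=None
        )
        assert log.stop_reason == "tolerance"
        assert log.n_epochs == 2

    def test_runs_to_max_epochs_without_plateau(self, monkeypatch):
        scripted = (0.1 * i for i in range(100))
        monkeypatch.setattr(
            model_mod, "_mean_slice_dice", lambda m, v: next(scripted)
        )
        model, data = self._tiny_setup()
        _, log = train_segmenter(
            model, data, data, TrainingConfig(max_epochs=3, seed=0), augment=None
        )
        assert log.stop_reason == "max_epochs"
        assert log.n_epochs == 3

    def test_empty_dataset_rejected(self):
        model, data = self._tiny_setup()
        with pytest.raises(ValueError):
            train_segmenter(model, [], data, TrainingConfig())

    def test_training_is_deterministic_under_seed(self):
        """Same seed, same data: bit-identical training log."""
        logs = []
        for _ in range(2):
            model, data = self._tiny_setup()
            _, log = train_segmenter(
                model, data, data, TrainingConfig(max_epochs=2, seed=3)
            )
            logs.append(log)
        assert logs[0].train_loss == logs[1].train_loss
        assert logs[0].val_dice == logs[1].val_dice


class TestSegmentVolume:
    def test_oracle_passthrough_recovers_truth(self, phantom_clean):
        p = phantom_clean
        oracle = OracleSegmenter(p.sac, p.extent)
        pred = segment_volume(p.ct, p.extent, oracle)
        assert np.array_equal(pred.voxels, p.sac.voxels)

    def test_outside_extent_is_zero(self, phantom_clean):
        p = phantom_clean
        pred = segment_volume(p.ct, p.extent, OracleSegmenter(p.sac, p.extent))
        assert pred.voxels[: p.extent.bottom].sum() == 0
        assert pred.voxels[p.extent.top + 1 :].sum() == 0

    def test_reassembly_invariant_to_presentation_order(self, phantom_clean):
        """Processing slices in bisected, sequential, or shuffled order
        yields the identical reassembled mask."""
        p = phantom_clean
        oracle = OracleSegmenter(p.sac, p.extent)

        def shuffled_plan(extent):
            plan = bisect_plan(extent)
            rng = np.random.default_rng(0)
            entries = list(plan.entries)
            rng.shuffle(entries)
            return type(plan)(entries=tuple(entries), split=plan.split)

        a = segment_volume(p.ct, p.extent, oracle, plan_fn=bisect_plan)
        b = segment_volume(p.ct, p.extent, oracle, plan_fn=sequential_plan)
        c = segment_volume(p.ct, p.extent, oracle, plan_fn=shuffled_plan)
        assert np.array_equal(a.voxels, b.voxels)
        assert np.array_equal(a.voxels, c.voxels)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        m = TinyUNet(seed=4)
        m.save(tmp_path / "ckpt.npz", config=TrainingConfig())
        loaded = TinyUNet.load(tmp_path / "ckpt.npz")
        slab = Slab(
            channels=(rng.random((3, 64, 64)) * 255).astype(np.uint8), target=0
        )
        assert np.array_equal(m.predict(slab), loaded.predict(slab))
        assert (tmp_path / "ckpt.npz.json").exists()

    def test_parameter_budget(self):
        assert TinyUNet(seed=0).n_parameters < 100_000
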