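"""Sampler balance, augmentation safety and the training/eval loops."""

from pathlib import Path

import numpy as np
import pytest

from esfpnet.data import DatasetIndex, DatasetRecord, load_dataset, split_by_case
from esfpnet.decoder import build_model
from esfpnet.nn import Tensor
from esfpnet.training import (
    TrainConfig,
    build_sampler,
    augment,
    evaluate,
    fit_arrays,
    load_checkpoint,
    save_checkpoint,
    train,
)


def _class_index(n_lesion, n_normal):
    records = [
        DatasetRecord(Path(f"l{i}.png"), Path(f"l{i}_m.png"), f"c{i}", "lesion")
        for i in range(n_lesion)
    ] + [
        DatasetRecord(Path(f"n{i}.png"), None, f"c{n_lesion + i}", "normal")
        for i in range(n_normal)
    ]
    return DatasetIndex(Path("."), records)


class TestSampler:
    def test_fixed_seed_reproduces_stream(self):
        index = _class_index(10, 20)
        cfg = TrainConfig()
        s1 = build_sampler(index, cfg, np.random.default_rng(5))
        s2 = build_sampler(index, cfg, np.random.default_rng(5))
        for _ in range(3):
            assert [r.frame for r in s1()] == [r.frame for r in s2()]

    def test_flat_draw_with_equal_weights_recovers_index_proportions(self):
        index = _class_index(30, 90)
        cfg = TrainConfig(sampling_weight_normal=1.0, sampling_weight_lesion=1.0)
        sampler = build_sampler(index, cfg, np.random.default_rng(0), stratify=False)
        lesions = sum(
            sum(r.label == "lesion" for r in sampler()) for _ in range(2000)
        )
        frac = lesions / (2000 * cfg.batch_size)
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_stratified_draw_balances_batches(self):
        # archive-like imbalance: 97 lesion / 223 normal frames
        index = _class_index(97, 223)
        cfg = TrainConfig()  # weights 4.95 / 1.43
        sampler = build_sampler(index, cfg, np.random.default_rng(1))
        lesions = [sum(r.label == "lesion" for r in sampler()) for _ in range(2000)]
        assert np.mean(lesions) == pytest.approx(8.0, abs=0.5)

    def test_flat_draw_follows_binomial_expectation(self):
        """Flat per-frame weighted draw: the lesion mass fraction is
        97*4.95 / (97*4.95 + 223*1.43) = 0.601, i.e. ~9.6 lesions per 16."""
        index = _class_index(97, 223)
        cfg = TrainConfig()
        sampler = build_sampler(index, cfg, np.random.default_rng(2), stratify=False)
        lesions = [sum(r.label == "lesion" for r in sampler()) for _ in range(2000)]
        expected = 16 * (97 * 4.95) / (97 * 4.95 + 223 * 1.43)
        assert np.mean(lesions) == pytest.approx(expected, abs=0.5)

    def test_single_class_warns_and_uniform(self):
        index = _class_index(0, 10)
        with pytest.warns(UserWarning, match="single class"):
            sampler = build_sampler(index, TrainConfig(), np.random.default_rng(0))
        assert len(sampler()) == TrainConfig().batch_size


class TestAugment:
    def _pair(self, rng):
        frame = rng.random((64, 64, 3)).astype(np.float32)
        mask = np.zeros((64, 64), np.uint8)
        mask[10:30, 20:40] = 1
        return frame, mask

    def test_mask_stays_binary_and_area_preserved_without_fine_rotation(self, rng):
        cfg = TrainConfig(fine_rotation_deg=0.0, jitter=0.0)
        frame, mask = self._pair(rng)
        for _ in range(10):
            f2, m2 = augment(frame, mask, cfg, rng)
            assert set(np.unique(m2)) <= {0, 1}
            assert m2.sum() == mask.sum()  # flips/rot90 move, never resample

    def test_geometry_applied_identically_to_frame_and_mask(self, rng):
        cfg = TrainConfig(jitter=0.0)
        frame, mask = self._pair(rng)
        # encode the mask into a frame channel; both must transform alike
        probe = np.repeat(mask[:, :, None].astype(np.float32), 3, axis=2)
        f2, m2 = augment(probe, mask, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal((f2[:, :, 0] > 0.5).astype(np.uint8), m2)

    def test_mask_untouched_by_photometric_jitter(self, rng):
        cfg = TrainConfig(flip_prob=0.0, fine_rotation_deg=0.0, jitter=0.4)
        frame, mask = self._pair(rng)
        f2, m2 = augment(frame, mask, cfg, rng)
        np.testing.assert_array_equal(m2, mask)
        assert not np.array_equal(f2, frame)  # jitter did act on the frame

    def test_double_flip_is_identity(self, rng):
        frame, mask = self._pair(rng)
        np.testing.assert_array_equal(frame[:, ::-1][:, ::-1], frame)
        np.testing.assert_array_equal(mask[::-1][::-1], mask)


class TestConfig:
    def test_odd_batch_rejected(self):
        with pytest.raises(ValueError, match="even"):
            TrainConfig(batch_size=15)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TrainConfig(sampling_weight_normal=0.0)

    def test_recipe_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-4
        assert (cfg.beta1, cfg.beta2) == (0.9, 0.999)
        assert cfg.epochs == 200 and cfg.batch_size == 16
        assert cfg.sampling_weight_normal == 1.43
        assert cfg.sampling_weight_lesion == 4.95


class TestTrainLoop:
    def test_shared_cases_are_a_hard_error(self):
        idx = _class_index(4, 4)
        model = build_model("T", seed=0)
        with pytest.raises(ValueError, match="share case"):
            train(model, idx, idx, TrainConfig(epochs=1))

    def test_zero_epochs_yield_empty_history(self, synth_root):
        index = load_dataset(synth_root)
        index, _ = split_by_case(index, rng=np.random.default_rng(0))
        model = build_model("T", seed=0)
        history, state = train(
            model, index.subset("train"), index.subset("val"),
            TrainConfig(epochs=0, image_side=32),
        )
        assert history.train_loss == [] and state == {}
        with pytest.raises(ValueError, match="empty"):
            history.best_epoch

    def test_short_run_records_history_and_best_checkpoint(self, synth_root, tmp_path):
        index = load_dataset(synth_root)
        index, _ = split_by_case(index, rng=np.random.default_rng(3))
        cfg = TrainConfig(epochs=2, batch_size=4, image_side=32, seed=0,
                          fine_rotation_deg=0.0)
        model = build_model("T", seed=0)
        history, best_state = train(
            model, index.subset("train"), index.subset("val"), cfg
        )
        assert len(history.train_loss) == 2
        assert history.best_epoch == int(np.argmax(history.val_mdice))
        assert all(np.isfinite(history.train_loss))
        ckpt = tmp_path / "best.npz"
        save_checkpoint(ckpt, best_state)
        restored = build_model("T", seed=9)
        restored.load_state_dict(load_checkpoint(ckpt))
        x = Tensor(np.zeros((1, 3, 32, 32), np.float32))
        model.load_state_dict(best_state)
        np.testing.assert_array_equal(
            restored.predict(x)[0], model.predict(x)[0]
        )

    def test_overfit_run_is_deterministic(self):
        imgs = np.random.default_rng(0).standard_normal((2, 3, 32, 32)).astype(np.float32)
        masks = np.zeros((2, 32, 32), np.uint8)
        masks[:, 8:24, 8:24] = 1
        curves = []
        for _ in range(2):
            model = build_model("T", seed=1)
            curve, _ = fit_arrays(model, imgs, masks, steps=3)
            curves.append(curve)
        assert curves[0] == curves[1]

    @pytest.mark.filterwarnings("ignore:invalid value encountered")
    def test_non_finite_loss_aborts_with_diagnostics(self):
        model = build_model("T", seed=0)
        model.decoder.mf_pred.bias.data[...] = np.inf
        imgs = np.zeros((1, 3, 32, 32), np.float32)
        masks = np.zeros((1, 32, 32), np.uint8)
        with pytest.raises((RuntimeError, FloatingPointError)):
            fit_arrays(model, imgs, masks, steps=1)


class TestEvaluate:
    def test_empty_predictor_scores_zero_recall_on_lesions(self, synth_root):
        index = load_dataset(synth_root)
        lesions = DatasetIndex(index.root, index.by_label("lesion"))
        model = build_model("T", seed=0)
        model.decoder.mf_pred.weight.data[...] = 0.0
        model.decoder.mf_pred.bias.data[...] = -50.0  # never predicts lesion
        summary = evaluate(model, lesions, image_side=32)
        assert summary.recall == 0.0
        assert summary.mdice == 0.0  # empty prediction against real lesions
        assert summary.counts.fp == 0

    def test_summary_matches_manual_aggregation(self, synth_root):
        from esfpnet.metrics import dataset_summary
        from esfpnet.training import evaluate_record

        index = load_dataset(synth_root)
        subset = DatasetIndex(index.root, index.records[:3])
        model = build_model("T", seed=0)
        rows = [evaluate_record(model, r, image_side=32) for r in subset]
        summary = evaluate(model, subset, image_side=32)
        manual = dataset_summary(rows)
        assert summary.mdice == manual.mdice
        assert summary.counts.tp == manual.counts.tp
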