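"""Splitting, cross-validation bookkeeping, and the training loop."""

import numpy as np
import pytest

import wbcseg.training as training_mod
from wbcseg import (
    TrainConfig,
    WBCSegmenter,
    cross_validate,
    kfold_partition,
    predict_mask,
    split_dataset,
    train,
)


class TestSplit:
    def test_floor_and_remainder_rule(self):
        ids = [f"s{i}" for i in range(10)]
        split = split_dataset(ids, (0.8, 0.1, 0.1), seed=0)
        sizes = {p: len(split.ids(p)) for p in ("train", "val", "test")}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_large_exact_multiplication(self):
        ids = [f"s{i}" for i in range(10600)]
        split = split_dataset(ids, (0.8, 0.1, 0.1), seed=1)
        assert len(split.ids("train")) == 8480
        assert len(split.ids("val")) == 1060
        assert len(split.ids("test")) == 1060

    def test_deterministic_and_partitioning(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_dataset(ids, seed=9)
        b = split_dataset(ids, seed=9)
        assert a.labels == b.labels
        all_ids = a.ids("train") + a.ids("val") + a.ids("test")
        assert sorted(all_ids) == sorted(ids)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b", "c"], (0.8, 0.1, 0.1), seed=0)


class TestKFold:
    def test_six_even_folds(self):
        folds = kfold_partition([f"s{i}" for i in range(12)], k=6, seed=0)
        assert sorted(len(folds.fold_ids(f)) for f in range(6)) == [2] * 6

    def test_union_and_disjointness(self):
        ids = [f"s{i}" for i in range(20)]
        folds = kfold_partition(ids, k=6, seed=2)
        seen = [i for f in range(6) for i in folds.fold_ids(f)]
        assert sorted(seen) == sorted(ids)  # each id in exactly one fold

    def test_remainder_distribution(self):
        folds = kfold_partition([f"s{i}" for i in range(13)], k=6, seed=3)
        sizes = sorted((len(folds.fold_ids(f)) for f in range(6)), reverse=True)
        assert sizes == [3, 2, 2, 2, 2, 2]

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(["a", "b"], k=6, seed=0)


class TestTrainingLoop:
    def test_single_epoch_bookkeeping(self, tiny_samples, tiny_train_config):
        from dataclasses import replace

        cfg = replace(tiny_train_config, epochs=1)
        results = train(tiny_samples[:8], tiny_samples[8:12], cfg)
        assert len(results.history) == 1
        row = results.history.iloc[0]
        assert np.isfinite(row.train_loss) and np.isfinite(row.val_loss)
        assert "Best epoch" in results.summary()

    def test_identical_seeds_identical_outcome(self, tiny_samples, tiny_train_config):
        r1 = train(tiny_samples[:8], tiny_samples[8:12], tiny_train_config)
        r2 = train(tiny_samples[:8], tiny_samples[8:12], tiny_train_config)
        assert abs(r1.best_val_iou - r2.best_val_iou) < 1e-6
        np.testing.assert_allclose(
            r1.history.train_loss.values, r2.history.train_loss.values, atol=1e-9
        )

    def test_learning_signal_loss_decreases(self, tiny_samples, tiny_model_config):
        cfg = TrainConfig(epochs=6, batch_size=4, seed=3, model=tiny_model_config)
        results = train(tiny_samples[:12], tiny_samples[12:16], cfg)
        h = results.history
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_no_leakage_stats_and_augment_touch_train_only(
        self, tiny_samples, tiny_model_config, monkeypatch
    ):
        seen_augment_ids = []
        real_augment = training_mod.augment

        def spy_augment(sample, config, seed):
            seen_augment_ids.append(sample.sample_id)
            return real_augment(sample, config, seed)

        stats_image_counts = []
        real_stats = training_mod.compute_global_stats

        def spy_stats(images, *a, **kw):
            images = list(images)
            stats_image_counts.append(len(images))
            return real_stats(images, *a, **kw)

        monkeypatch.setattr(training_mod, "augment", spy_augment)
        monkeypatch.setattr(training_mod, "compute_global_stats", spy_stats)

        train_part, val_part = tiny_samples[:8], tiny_samples[8:12]
        cfg = TrainConfig(epochs=1, batch_size=4, seed=1, model=tiny_model_config)
        train(train_part, val_part, cfg)

        train_ids = {s.sample_id for s in train_part}
        assert set(seen_augment_ids) <= train_ids and seen_augment_ids
        assert stats_image_counts == [len(train_part)]

    def test_predict_mask_thresholds_and_checkpoint(
        self, tmp_path, tiny_samples, tiny_train_config
    ):
        results = train(tiny_samples[:8], tiny_samples[8:12], tiny_train_config)
        image = tiny_samples[12].image
        assert results.predict(image, threshold=1e-9).all()  # ~all foreground
        assert not results.predict(image, threshold=1 - 1e-9).any()

        path = tmp_path / "model.ckpt.npz"
        results.save(str(path))
        from_ckpt = predict_mask(str(path), image, threshold=0.5)
        direct = results.predict(image, threshold=0.5)
        np.testing.assert_array_equal(from_ckpt, direct)

    def test_empty_partition_rejected(self, tiny_samples, tiny_train_config):
        with pytest.raises(ValueError):
            WBCSegmenter([], tiny_samples[:2], tiny_train_config)


class TestCrossValidate:
    def test_two_fold_bookkeeping(self, tiny_samples, tiny_train_config):
        cv = cross_validate(tiny_samples[:20], k=2, config=tiny_train_config)
        assert len(cv.fold_reports) == 2
        tested = [
            sid for report in cv.fold_reports for sid in report.per_sample.index
        ]
        assert sorted(tested) == sorted(s.sample_id for s in tiny_samples[:20])
        fold_ious = [r.aggregates["iou"] for r in cv.fold_reports]
        assert cv.aggregate.loc["iou", "mean"] == pytest.approx(
            np.mean(fold_ious), abs=1e-9
        )
        assert "iou" in cv.summary()
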