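"""Dataset splitting, the training loop, and the cross-validation harness.

The modelling surface follows the estimator/results idiom: a
:class:`WBCSegmenter` is constructed from training and validation samples
plus a :class:`TrainConfig`; its :meth:`~WBCSegmenter.fit` runs the seeded
end-to-end pipeline — augment (training partition only) -> resize ->
normalize (stats from the training partition) -> minimize the compound
BCE+Tversky loss with Adam — and returns a :class:`SegmentationResults`
holding the best-validation-IoU weights, the per-epoch history, and
``summary()``/``predict()``/``evaluate()``/``save()`` methods.  The
procedural :func:`train` and :func:`cross_validate` entry points wrap it.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as seg_metrics
from .losses import LossConfig, combined_loss, combined_loss_grad
from .metrics import MetricReport, binarize, evaluate_dataset
from .model import (
    ModelConfig,
    SegmentationUNet,
    build_segmentation_network,
    count_parameters,
)
from .nn import Adam
from .preprocessing import (
    AugmentConfig,
    NormalizationStats,
    augment,
    compute_global_stats,
    normalize,
    resize_to_model,
)
from .synthetic import RenderedSample

__all__ = [
    "SplitAssignment",
    "FoldAssignment",
    "TrainConfig",
    "WBCSegmenter",
    "SegmentationResults",
    "CrossValidationResults",
    "split_dataset",
    "kfold_partition",
    "train",
    "cross_validate",
    "predict_mask",
]


# ---------------------------------------------------------------------------
# deterministic partitioning


@dataclass(frozen=True)
class SplitAssignment:
    """Deterministic train/val/test partition of sample ids."""

    ratios: tuple[float, float, float]
    labels: dict[str, str]  # sample_id -> "train" | "val" | "test"
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [s for s, p in self.labels.items() if p == partition]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def split_dataset(
    sample_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Seeded shuffle, then floor(r*n) per partition with the remainder to train.

    The default is the 80/10/10 train/validation/test protocol.
    """
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to split three ways")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    n_val = int(math.floor(ratios[1] * n))
    n_test = int(math.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for ratios {ratios}: empty partition")
    order = list(sample_ids)
    np.random.default_rng(seed).shuffle(order)
    labels = {}
    for i, sid in enumerate(order):
        if i < n_train:
            labels[sid] = "train"
        elif i < n_train + n_val:
            labels[sid] = "val"
        else:
            labels[sid] = "test"
    return SplitAssignment(ratios=tuple(ratios), labels=labels, seed=seed)


def kfold_partition(
    sample_ids: Sequence[str], k: int = 6, seed: int = 0
) -> FoldAssignment:
    """Seeded shuffle then round-robin fold assignment (six folds by default).

    Every sample lands in exactly one fold and fold sizes differ by at most 1,
    so across the k train/test rotations each sample is tested exactly once.
    """
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    order = list(sample_ids)
    np.random.default_rng(seed).shuffle(order)
    return FoldAssignment(
        k=k, fold_of={sid: i % k for i, sid in enumerate(order)}, seed=seed
    )


# ---------------------------------------------------------------------------
# training configuration


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 5  # early stopping on validation IoU
    binarize_threshold: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# tensor preparation


def _prepare(
    samples: Sequence[RenderedSample], side: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Resize to the model side; returns resized images (HWC) and masks (NHW)."""
    images, masks = [], []
    for s in samples:
        img = s.image.astype(np.float64)
        msk = s.mask
        if img.shape[0] != side or img.shape[1] != side:
            img = resize_to_model(img, side, is_mask=False)
            msk = resize_to_model(msk, side, is_mask=True)
        images.append(img)
        masks.append(msk.astype(np.float64))
    return images, np.stack(masks)


def _to_nchw(images: Sequence[np.ndarray], stats: NormalizationStats) -> np.ndarray:
    arr = np.stack([normalize(img, stats) for img in images])
    return arr.transpose(0, 3, 1, 2)


def _augment_seed(master: int, epoch: int, index: int) -> int:
    return int(
        np.random.SeedSequence([master, epoch, index]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


# ---------------------------------------------------------------------------
# results object


@dataclass
class SegmentationResults:
    """Fitted-model container: best weights, stats, history, diagnostics."""

    network: SegmentationUNet
    config: TrainConfig
    stats: NormalizationStats
    history: pd.DataFrame
    best_epoch: int
    best_val_iou: float

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map at the model's working resolution."""
        side = self.config.model.input_side
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[0] != side or img.shape[1] != side:
            img = resize_to_model(img, side, is_mask=False)
        x = normalize(img, self.stats).transpose(2, 0, 1)[None]
        return self.network.forward(x, training=False)[0, 0]

    def predict(
        self,
        image: np.ndarray,
        threshold: float | None = None,
        restore_size: bool = True,
    ) -> np.ndarray:
        """Binary WBC mask for one RGB image."""
        thr = self.config.binarize_threshold if threshold is None else threshold
        prob = self.predict_proba(image)
        mask = binarize(prob, thr)
        orig = np.asarray(image).shape[:2]
        if restore_size and orig != mask.shape:
            mask = resize_to_model(mask, orig[0], is_mask=True)  # square inputs
        return mask

    def evaluate(
        self,
        samples: Sequence[RenderedSample],
        tolerance: float = seg_metrics.DEFAULT_BOUNDARY_TOLERANCE,
    ) -> MetricReport:
        side = self.config.model.input_side
        images, masks = _prepare(samples, side)
        x = _to_nchw(images, self.stats)
        preds = []
        bs = self.config.batch_size
        for i in range(0, len(x), bs):
            preds.append(self.network.forward(x[i : i + bs], training=False))
        prob = np.concatenate(preds)[:, 0]
        pairs = [
            (binarize(prob[i], self.config.binarize_threshold), masks[i].astype(np.uint8))
            for i in range(len(samples))
        ]
        return evaluate_dataset(
            pairs, tolerance, sample_ids=[s.sample_id for s in samples]
        )

    def save(self, path: str) -> None:
        from . import io as wio

        wio.save_checkpoint(
            path,
            self.network,
            self.stats,
            extra={
                "best_epoch": self.best_epoch,
                "best_val_iou": self.best_val_iou,
                "binarize_threshold": self.config.binarize_threshold,
            },
        )

    def summary(self) -> str:
        """Human-readable fit summary: architecture, data stats, history tail."""
        ns = count_parameters(self.network)
        cfg = self.config
        lines = [
            "        WBC Residual-UNet Segmentation Results",
            "=" * 56,
            f"Input side:          {cfg.model.input_side}",
            f"Encoder filters:     {cfg.model.scaled_encoder_filters()}",
            f"Decoder filters:     {cfg.model.scaled_decoder_filters()}",
            f"Trainable params:    {ns.trainable_params:,}",
            f"Nontrainable params: {ns.nontrainable_params:,}",
            f"Optimizer:           {cfg.optimizer} (lr={cfg.learning_rate})",
            f"Loss:                BCE*{cfg.loss.bce_weight} + "
            f"Tversky*{cfg.loss.tversky_weight} "
            f"(alpha={cfg.loss.tversky_alpha}, beta={cfg.loss.tversky_beta})",
            f"Epochs run:          {len(self.history)} / {cfg.epochs}",
            f"Best epoch:          {self.best_epoch} "
            f"(validation IoU {self.best_val_iou:.4f})",
            f"Normalization:       mean={self.stats.global_mean:.3f}, "
            f"std={self.stats.global_std:.3f}, eps={self.stats.epsilon:g}",
            "-" * 56,
            self.history.tail(5).to_string(index=False),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the estimator


class WBCSegmenter:
    """Residual-UNet segmentation model bound to training/validation data."""

    def __init__(
        self,
        train_samples: Sequence[RenderedSample],
        val_samples: Sequence[RenderedSample],
        config: TrainConfig | None = None,
    ) -> None:
        if not train_samples or not val_samples:
            raise ValueError("training and validation sets must be nonempty")
        self.train_samples = list(train_samples)
        self.val_samples = list(val_samples)
        self.config = config or TrainConfig()

    @classmethod
    def from_split(
        cls,
        samples: Sequence[RenderedSample],
        split: SplitAssignment,
        config: TrainConfig | None = None,
    ) -> "WBCSegmenter":
        by_id = {s.sample_id: s for s in samples}
        return cls(
            [by_id[i] for i in split.ids("train")],
            [by_id[i] for i in split.ids("val")],
            config,
        )

    def fit(self, verbose: bool = False) -> SegmentationResults:
        cfg = self.config
        side = cfg.model.input_side

        # Normalization stats come from the (un-augmented) training partition.
        train_images_resized, _ = _prepare(self.train_samples, side)
        stats = compute_global_stats(train_images_resized)

        val_images, val_masks = _prepare(self.val_samples, side)
        x_val = _to_nchw(val_images, stats)

        net = build_segmentation_network(cfg.model, seed=cfg.seed)
        net.set_dropout_seed(cfg.seed + 2)
        opt = Adam(net.all_layers(), lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(cfg.seed + 3)

        history_rows = []
        best_val_iou = -np.inf
        best_epoch = -1
        best_state = None
        stale = 0

        n = len(self.train_samples)
        for epoch in range(cfg.epochs):
            # augment -> resize -> normalize, fresh draws each epoch
            if cfg.augment.enabled:
                epoch_samples = [
                    augment(s, cfg.augment, _augment_seed(cfg.seed, epoch, i))
                    for i, s in enumerate(self.train_samples)
                ]
            else:
                epoch_samples = self.train_samples
            images, masks = _prepare(epoch_samples, side)
            x = _to_nchw(images, stats)

            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, tb = x[idx], masks[idx][:, None]
                prob = net.forward(xb, training=True)
                loss = combined_loss(prob, tb, cfg.loss)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {loss!r} at "
                        f"epoch {epoch}, batch {n_batches}"
                    )
                net.backward(combined_loss_grad(prob, tb, cfg.loss))
                opt.step()
                epoch_loss += loss
                n_batches += 1

            val_loss, val_iou = self._validate(net, x_val, val_masks, cfg)
            history_rows.append(
                {
                    "epoch": epoch,
                    "train_loss": epoch_loss / n_batches,
                    "val_loss": val_loss,
                    "val_iou": val_iou,
                }
            )
            if verbose:
                print(
                    f"epoch {epoch:3d}  train_loss {epoch_loss / n_batches:.4f}  "
                    f"val_loss {val_loss:.4f}  val_iou {val_iou:.4f}"
                )
            if val_iou > best_val_iou:
                best_val_iou = val_iou
                best_epoch = epoch
                best_state = [
                    {k: v.copy() for k, v in layer.state_arrays().items()}
                    for layer in net.all_layers()
                ]
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break

        if best_state is not None:  # restore the best-validation-IoU weights
            for layer, snap in zip(net.all_layers(), best_state):
                for k, v in layer.state_arrays().items():
                    v[...] = snap[k]

        return SegmentationResults(
            network=net,
            config=cfg,
            stats=stats,
            history=pd.DataFrame(history_rows),
            best_epoch=best_epoch,
            best_val_iou=float(best_val_iou),
        )

    @staticmethod
    def _validate(
        net: SegmentationUNet,
        x_val: np.ndarray,
        val_masks: np.ndarray,
        cfg: TrainConfig,
    ) -> tuple[float, float]:
        losses, ious = [], []
        for i in range(0, len(x_val), cfg.batch_size):
            xb = x_val[i : i + cfg.batch_size]
            tb = val_masks[i : i + cfg.batch_size][:, None]
            prob = net.forward(xb, training=False)
            losses.append(combined_loss(prob, tb, cfg.loss))
            for j in range(len(xb)):
                c = seg_metrics.confusion_counts(
                    binarize(prob[j, 0], cfg.binarize_threshold),
                    tb[j, 0].astype(np.uint8),
                )
                ious.append(seg_metrics.iou(c))
        return float(np.mean(losses)), float(np.mean(ious))


def train(
    train_set: Sequence[RenderedSample],
    val_set: Sequence[RenderedSample],
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> SegmentationResults:
    """Seeded end-to-end training run; returns the fitted results object."""
    return WBCSegmenter(train_set, val_set, config).fit(verbose=verbose)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResults:
    fold_reports: list[MetricReport]
    aggregate: pd.DataFrame  # index metric, columns mean / sd

    def summary(self) -> str:
        return self.aggregate.round(4).to_string()


def cross_validate(
    dataset: Sequence[RenderedSample],
    k: int = 6,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> CrossValidationResults:
    """k-fold rotation: train on k-1 folds, test on the held-out fold.

    A small validation slice (10%, at least one sample) is carved from each
    fold's training pool for early stopping.  The aggregate row is the
    unweighted mean and standard deviation of each metric across folds.
    """
    config = config or TrainConfig()
    ids = [s.sample_id for s in dataset]
    by_id = {s.sample_id: s for s in dataset}
    folds = kfold_partition(ids, k=k, seed=config.seed)

    reports = []
    for fold in range(k):
        test_ids = set(folds.fold_ids(fold))
        pool = [by_id[i] for i in ids if i not in test_ids]
        n_val = max(1, len(pool) // 10)
        train_part, val_part = pool[:-n_val], pool[-n_val:]
        results = train(train_part, val_part, config, verbose=verbose)
        reports.append(results.evaluate([by_id[i] for i in sorted(test_ids)]))

    table = pd.DataFrame([r.aggregates for r in reports])
    aggregate = pd.DataFrame({"mean": table.mean(), "sd": table.std(ddof=1)})
    return CrossValidationResults(fold_reports=reports, aggregate=aggregate)


def predict_mask(
    checkpoint,
    image: np.ndarray,
    threshold: float = 0.5,
    restore_size: bool = True,
) -> np.ndarray:
    """Segment one image from a checkpoint path or a fitted results object."""
    if isinstance(checkpoint, SegmentationResults):
        return checkpoint.predict(image, threshold, restore_size)
    from . import io as wio

    network, stats, extra = wio.load_checkpoint(checkpoint)
    shell = SegmentationResults(
        network=network,
        config=TrainConfig(model=network.config),
        stats=stats,
        history=pd.DataFrame(),
        best_epoch=int(extra.get("best_epoch", -1)),
        best_val_iou=float(extra.get("best_val_iou", float("nan"))),
    )
    return shell.predict(image, threshold, restore_size)
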