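"""Compound training loss: binary cross-entropy plus Tversky loss.

The training objective is the unweighted sum L = L_BCE + L_T.  The Tversky
term is one minus a smoothed generalized overlap index whose alpha and beta
weights penalize false positives and false negatives; at alpha = beta = 0.5
it reduces exactly to the soft Dice loss, which is the default here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "bce_loss",
    "bce_loss_grad",
    "tversky_loss",
    "tversky_loss_grad",
    "combined_loss",
    "combined_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    bce_weight: float = 1.0
    tversky_weight: float = 1.0
    tversky_alpha: float = 0.5  # false-positive penalty
    tversky_beta: float = 0.5  # false-negative penalty
    smooth: float = 1.0
    clip_epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.bce_weight < 0 or self.tversky_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if not 0.0 < self.clip_epsilon < 0.5:
            raise ValueError("clip_epsilon must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        return {
            "bce_weight": self.bce_weight,
            "tversky_weight": self.tversky_weight,
            "tversky_alpha": self.tversky_alpha,
            "tversky_beta": self.tversky_beta,
            "smooth": self.smooth,
            "clip_epsilon": self.clip_epsilon,
        }


def _check(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def bce_loss(
    pred: np.ndarray, target: np.ndarray, clip_epsilon: float = 1e-7
) -> float:
    """Mean pixelwise binary cross-entropy with probability clipping."""
    pred, target = _check(pred, target)
    p = np.clip(pred, clip_epsilon, 1.0 - clip_epsilon)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def bce_loss_grad(
    pred: np.ndarray, target: np.ndarray, clip_epsilon: float = 1e-7
) -> np.ndarray:
    """d(bce)/d(pred); zero where the clip saturates."""
    pred, target = _check(pred, target)
    p = np.clip(pred, clip_epsilon, 1.0 - clip_epsilon)
    g = (-target / p + (1.0 - target) / (1.0 - p)) / pred.size
    inside = (pred > clip_epsilon) & (pred < 1.0 - clip_epsilon)
    return g * inside


def _tversky_terms(pred, target, config: LossConfig):
    inter = float(np.sum(pred * target))
    fp = float(np.sum(pred * (1.0 - target)))
    fn = float(np.sum((1.0 - pred) * target))
    num = inter + config.smooth
    den = inter + config.tversky_alpha * fp + config.tversky_beta * fn + config.smooth
    return num, den


def tversky_loss(
    pred: np.ndarray, target: np.ndarray, config: LossConfig | None = None
) -> float:
    """1 - (|PT| + s) / (|PT| + alpha|P(1-T)| + beta|(1-P)T| + s), in [0, 1]."""
    config = config or LossConfig()
    pred, target = _check(pred, target)
    num, den = _tversky_terms(pred, target, config)
    return float(1.0 - num / den)


def tversky_loss_grad(
    pred: np.ndarray, target: np.ndarray, config: LossConfig | None = None
) -> np.ndarray:
    config = config or LossConfig()
    pred, target = _check(pred, target)
    num, den = _tversky_terms(pred, target, config)
    dnum = target
    dden = target + config.tversky_alpha * (1.0 - target) - config.tversky_beta * target
    return -(dnum * den - num * dden) / den**2


def combined_loss(
    pred: np.ndarray, target: np.ndarray, config: LossConfig | None = None
) -> float:
    """bce_weight * L_BCE + tversky_weight * L_T."""
    config = config or LossConfig()
    return config.bce_weight * bce_loss(
        pred, target, config.clip_epsilon
    ) + config.tversky_weight * tversky_loss(pred, target, config)


def combined_loss_grad(
    pred: np.ndarray, target: np.ndarray, config: LossConfig | None = None
) -> np.ndarray:
    config = config or LossConfig()
    return config.bce_weight * bce_loss_grad(
        pred, target, config.clip_epsilon
    ) + config.tversky_weight * tversky_loss_grad(pred, target, config)
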