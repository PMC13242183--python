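"""Weighted-average decision-level fusion of two modality classifiers.

Given one fold's train-split accuracies acc_R (expression) and acc_C
(copy number), the fusion rule forms a sharpness parameter

    alpha = |e^{acc_C} - e^{acc_R}| * k

with scaling factor k (default 10), then softmax weights

    w_R = e^{alpha * acc_R} / (e^{alpha * acc_R} + e^{alpha * acc_C})
    w_C = 1 - w_R

and fuses each validation sample's class-probability pairs as the convex
combination  p_F = w_R * p_R + w_C * p_C,  predicting the class with the
larger fused probability.  Equal accuracies give alpha = 0 and exactly
equal weights, i.e. ordinary soft voting; as k grows the fused output
converges to the more accurate modality's output.  Hard voting and soft
voting baselines live here too.

The softmax is evaluated in the max-subtracted form, so accuracies in [0, 1]
with k up to ~1e6 cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bench import FoldPrediction

__all__ = [
    "FusionWeights",
    "FusedPrediction",
    "compute_alpha",
    "compute_weights",
    "fuse_probabilities",
    "fuse_fold",
    "soft_vote",
    "hard_vote",
    "sweep_k",
    "DEFAULT_K_SCALE",
]

DEFAULT_K_SCALE = 10.0
_PROBA_TOL = 1e-6


@dataclass(frozen=True)
class FusionWeights:
    """One fold's fusion parameters."""

    alpha: float
    w_rna: float
    w_cnv: float
    k_scale: float

    def __post_init__(self) -> None:
        if abs(self.w_rna + self.w_cnv - 1.0) > 1e-12:
            raise ValueError("w_rna + w_cnv must equal 1")
        if self.alpha < 0 or self.k_scale <= 0:
            raise ValueError("alpha must be >= 0 and k_scale > 0")


@dataclass(frozen=True)
class FusedPrediction:
    sample_id: str
    p_fused_y0: float
    p_fused_y1: float
    label: int


def _check_accuracy(acc: float, name: str) -> None:
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {acc}")


def compute_alpha(acc_rna: float, acc_cnv: float, k_scale: float = DEFAULT_K_SCALE) -> float:
    """Sharpness of the weighting: k times the gap between the exponentiated
    accuracies.  Zero iff the accuracies are equal."""
    _check_accuracy(acc_rna, "acc_rna")
    _check_accuracy(acc_cnv, "acc_cnv")
    if k_scale <= 0:
        raise ValueError("k_scale must be positive")
    return abs(np.exp(acc_cnv) - np.exp(acc_rna)) * k_scale


def compute_weights(acc_rna: float, acc_cnv: float, alpha: float) -> tuple[float, float]:
    """Softmax of (alpha*acc_rna, alpha*acc_cnv), max-subtracted for stability."""
    _check_accuracy(acc_rna, "acc_rna")
    _check_accuracy(acc_cnv, "acc_cnv")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    a_r, a_c = alpha * acc_rna, alpha * acc_cnv
    m = max(a_r, a_c)
    e_r, e_c = np.exp(a_r - m), np.exp(a_c - m)
    w_rna = float(e_r / (e_r + e_c))
    return w_rna, 1.0 - w_rna


def fusion_weights(
    acc_rna: float, acc_cnv: float, k_scale: float = DEFAULT_K_SCALE
) -> FusionWeights:
    """Convenience: alpha then weights in one step."""
    alpha = compute_alpha(acc_rna, acc_cnv, k_scale)
    w_rna, w_cnv = compute_weights(acc_rna, acc_cnv, alpha)
    return FusionWeights(alpha=alpha, w_rna=w_rna, w_cnv=w_cnv, k_scale=k_scale)


def _check_pair(p: Sequence[float], name: str) -> tuple[float, float]:
    p0, p1 = float(p[0]), float(p[1])
    if abs(p0 + p1 - 1.0) > _PROBA_TOL or p0 < -_PROBA_TOL or p1 < -_PROBA_TOL:
        raise ValueError(f"{name} = ({p0}, {p1}) is not a normalized probability pair")
    return p0, p1


def fuse_probabilities(
    p_rna: Sequence[float],
    p_cnv: Sequence[float],
    weights: FusionWeights,
    sample_id: str = "",
) -> FusedPrediction:
    """Per-class convex combination; label = argmax, ties to class 0."""
    r0, r1 = _check_pair(p_rna, "p_rna")
    c0, c1 = _check_pair(p_cnv, "p_cnv")
    p0 = weights.w_rna * r0 + weights.w_cnv * c0
    p1 = weights.w_rna * r1 + weights.w_cnv * c1
    label = 1 if p1 > p0 else 0
    return FusedPrediction(sample_id=sample_id, p_fused_y0=p0, p_fused_y1=p1, label=label)


def fuse_fold(
    pred_rna: FoldPrediction,
    pred_cnv: FoldPrediction,
    k_scale: float = DEFAULT_K_SCALE,
) -> tuple[list[FusedPrediction], FusionWeights]:
    """Fuse one aligned fold: weights come once from the two train accuracies
    and apply to every validation sample."""
    if pred_rna.validation_ids != pred_cnv.validation_ids:
        raise ValueError(
            f"fold {pred_rna.fold_index}: validation sample IDs differ between modalities"
        )
    w = fusion_weights(pred_rna.train_accuracy, pred_cnv.train_accuracy, k_scale)
    fused = [
        fuse_probabilities(pr, pc, w, sample_id=sid)
        for sid, pr, pc in zip(pred_rna.validation_ids, pred_rna.proba, pred_cnv.proba)
    ]
    return fused, w


def soft_vote(
    p_rna: Sequence[float], p_cnv: Sequence[float], sample_id: str = ""
) -> FusedPrediction:
    """Equal-weight probability averaging (conventional soft voting)."""
    w = FusionWeights(alpha=0.0, w_rna=0.5, w_cnv=0.5, k_scale=DEFAULT_K_SCALE)
    return fuse_probabilities(p_rna, p_cnv, w, sample_id=sample_id)


def hard_vote(
    label_rna: int,
    label_cnv: int,
    p_rna: Sequence[float] | None = None,
    p_cnv: Sequence[float] | None = None,
) -> int:
    """Majority vote over the two modality labels.  A 1-1 tie falls back to
    the soft-vote label (requires the probability pairs)."""
    if label_rna == label_cnv:
        return int(label_rna)
    if p_rna is None or p_cnv is None:
        raise ValueError("tied hard vote needs probability pairs for the tie-break")
    return soft_vote(p_rna, p_cnv).label


def sweep_k(
    preds_rna: Sequence[FoldPrediction],
    preds_cnv: Sequence[FoldPrediction],
    true_labels: dict[str, int],
    k_grid: Sequence[float],
) -> list[tuple[float, float]]:
    """Fused accuracy (pooled over folds) for each scaling factor in the grid.

    Returns ``[(k, accuracy), ...]`` in grid order.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be non-empty")
    curve = []
    for k in k_grid:
        correct = total = 0
        for pr, pc in zip(preds_rna, preds_cnv):
            fused, _ = fuse_fold(pr, pc, k_scale=k)
            for f in fused:
                correct += int(f.label == true_labels[f.sample_id])
                total += 1
        curve.append((float(k), correct / total))
    return curve
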