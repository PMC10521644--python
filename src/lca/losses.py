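"""Softmax and class-weighted cross-entropy for imbalanced multiclass data.

The weighting scheme is inverse normalized class frequency: with ``N`` total
training samples and ``n_i`` samples in class ``i``, the class weight is
``w_i = N / n_i``, and the per-sample loss is ``L = -sum_i w_i p_i log(p^_i)``
with one-hot ground truth ``p`` and softmax probabilities ``p^``.  Under a
balanced dataset every weight equals the number of classes, so the weighted
loss is the standard cross-entropy uniformly rescaled by ``C``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ClassWeights",
    "PredictionBatch",
    "softmax_probs",
    "class_weights",
    "cross_entropy",
    "weighted_cross_entropy",
]

LOG_EPS = 1e-12  # clamp for log(p^) when the true-class probability underflows


@dataclasses.dataclass(frozen=True)
class ClassWeights:
    """Inverse-normalized-class-frequency weights, w_i = N / n_i."""

    weights: np.ndarray
    class_counts: np.ndarray
    total: int

    @property
    def num_classes(self) -> int:
        return len(self.weights)


@dataclasses.dataclass(frozen=True)
class PredictionBatch:
    """Logits plus one-hot labels for a batch; probabilities derived lazily."""

    logits: np.ndarray  # (batch, C)
    labels: np.ndarray  # (batch, C) one-hot

    def __post_init__(self):
        if self.logits.shape != self.labels.shape:
            raise ValueError("logits and labels must share shape (batch, C)")
        row_sums = self.labels.sum(axis=1)
        if not np.all(row_sums == 1) or not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be one-hot rows")

    @property
    def probabilities(self) -> np.ndarray:
        return softmax_probs(self.logits)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by max-shift.

    Shift-invariant: adding a constant to every logit of a row leaves the
    output unchanged, so logits up to +-1e4 are safe.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def class_weights(class_counts) -> ClassWeights:
    """w_i = N / n_i from per-class training-set counts.

    Weights must be computed from the training split only, never from the
    validation split, to avoid leakage.
    """
    counts = np.asarray(class_counts, dtype=np.int64)
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1 (weight undefined otherwise)")
    total = int(counts.sum())
    return ClassWeights(weights=total / counts, class_counts=counts, total=total)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), num_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy(probabilities, labels_onehot, reduction: str = "mean") -> float:
    """Standard multiclass cross-entropy -sum_i p_i log p^_i."""
    return weighted_cross_entropy(probabilities, labels_onehot, None, reduction)


def weighted_cross_entropy(
    probabilities,
    labels_onehot,
    weights: ClassWeights | np.ndarray | None = None,
    reduction: str = "mean",
) -> float:
    """Class-weighted cross-entropy, L = -sum_i w_i p_i log p^_i.

    Parameters
    ----------
    probabilities : (batch, C) softmax outputs (or a :class:`PredictionBatch`).
    labels_onehot : (batch, C) one-hot ground truth; ignored when a
        :class:`PredictionBatch` is passed.
    weights : per-class weights; ``None`` means unit weights, which makes this
        identical to the unweighted loss.
    reduction : "mean" (default) or "sum" over the batch.
    """
    if isinstance(probabilities, PredictionBatch):
        batch = probabilities
        probabilities, labels_onehot = batch.probabilities, batch.labels
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels_onehot = np.asarray(labels_onehot, dtype=np.float64)
    if probabilities.shape != labels_onehot.shape:
        raise ValueError("probabilities and labels must share shape")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if weights is None:
        w = np.ones(probabilities.shape[1])
    elif isinstance(weights, ClassWeights):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=np.float64)
    logp = np.log(np.clip(probabilities, LOG_EPS, None))
    per_sample = -(w * labels_onehot * logp).sum(axis=1)
    return float(per_sample.mean() if reduction == "mean" else per_sample.sum())
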