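"""Scoring: accuracy, Cohen's kappa, confusion and Markov transition
matrices, and subject-resampled bootstrap comparisons between systems.

Resampling is at the subject level (not the epoch level) by default:
epochs of one neonate are correlated, so epoch-level resampling would
understate the uncertainty.  Epochs for which a system produced no
estimate ("void", encoded as grade 0) are scored as incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .model import GRADES

__all__ = [
    "ConfusionMatrix",
    "TransitionMatrix",
    "confusion",
    "accuracy_and_kappa",
    "transition_matrix",
    "bootstrap_accuracy_difference",
    "VOID",
]

#: sentinel grade for epochs where the system produced no estimate
VOID = 0


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = reference grade, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] < self.counts.shape[0]:
            raise ValueError(
                "confusion matrix must be square (plus an optional trailing "
                "void column)"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionMatrix:
    """Row-stochastic grade-transition probabilities; nan rows = unobserved."""

    probs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


def confusion(truth: Sequence[int], pred: Sequence[int]) -> ConfusionMatrix:
    """Confusion matrix over grades 1-4.

    Void predictions (grade 0), if present, occupy a trailing extra
    column: they count towards the total but never as correct.
    """
    truth = np.asarray(truth, int)
    pred = np.asarray(pred, int)
    if np.any(pred == VOID):
        counts = _sk_confusion(truth, pred, labels=[*GRADES, VOID])
        return ConfusionMatrix(counts=counts[: len(GRADES), :])
    return ConfusionMatrix(counts=_sk_confusion(truth, pred, labels=list(GRADES)))


def accuracy_and_kappa(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy in %, Cohen's kappa) from the confusion counts.

    accuracy = 100 * trace / total; kappa = (p_o - p_e) / (1 - p_e) with
    the chance agreement p_e from the row/column marginals.  Returns nan
    for kappa in the degenerate p_e = 1 case.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    k = min(c.shape)
    p_o = np.trace(c[:k, :k]) / total
    p_e = float((c.sum(axis=1)[:k] * c.sum(axis=0)[:k]).sum()) / total**2
    accuracy = 100.0 * p_o
    if abs(1.0 - p_e) < 1e-12:
        return accuracy, float("nan")
    return accuracy, (p_o - p_e) / (1.0 - p_e)


def transition_matrix(sequences: Sequence[Sequence[int]]) -> TransitionMatrix:
    """Maximum-likelihood Markov estimate pooled over per-subject sequences.

    probs[i, j] = count(i -> j over consecutive pairs) / count(i -> .).
    Postnatal age is treated as categorical: all consecutive pairs pool
    regardless of the gap between time points.
    """
    n = len(GRADES)
    counts = np.zeros((n, n), dtype=int)
    for seq in sequences:
        seq = [int(g) for g in seq]
        if len(seq) < 2:
            raise ValueError("each sequence needs at least 2 time points")
        for a, b in zip(seq[:-1], seq[1:]):
            if a not in GRADES or b not in GRADES:
                raise ValueError(f"unknown grade in sequence: {a} -> {b}")
            counts[a - 1, b - 1] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.maximum(row, 1), np.nan)
    return TransitionMatrix(probs=probs, counts=counts)


def bootstrap_accuracy_difference(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    truth: Sequence[int],
    subject_ids: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    subject_level: bool = True,
) -> dict:
    """Bootstrap the accuracy difference (A - B) with subject resampling.

    Subjects are resampled with replacement; both accuracies are
    recomputed per replicate over the resampled subjects' epochs.  Returns
    the point difference (in % points), the percentile 95% CI, the
    two-sided p (fraction of replicates crossing zero, doubled, floored at
    1/n_boot), and the replicate vector.
    """
    pred_a = np.asarray(pred_a, int)
    pred_b = np.asarray(pred_b, int)
    truth = np.asarray(truth, int)
    subject_ids = np.asarray(subject_ids)
    if not (pred_a.shape == pred_b.shape == truth.shape == subject_ids.shape):
        raise ValueError("predictions, truth and subject ids must align")
    subjects = np.unique(subject_ids)
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects to resample")
    hit_a = (pred_a == truth).astype(float)
    hit_b = (pred_b == truth).astype(float)
    groups = [np.flatnonzero(subject_ids == s) for s in subjects]

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    units = groups if subject_level else [np.array([i]) for i in range(truth.size)]
    for r in range(n_boot):
        pick = rng.integers(0, len(units), size=len(units))
        idx = np.concatenate([units[p] for p in pick])
        reps[r] = 100.0 * (hit_a[idx].mean() - hit_b[idx].mean())
    point = 100.0 * (hit_a.mean() - hit_b.mean())
    ci = tuple(np.percentile(reps, [2.5, 97.5]))
    p = 2.0 * min((reps <= 0).mean(), (reps >= 0).mean())
    p = min(max(p, 1.0 / n_boot), 1.0)
    return {
        "difference": point,
        "ci95": ci,
        "p": p,
        "replicates": reps,
        "n_boot": n_boot,
    }
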