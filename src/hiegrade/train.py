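"""Training of the grading network.

Optimiser recipe: categorical cross-entropy, stochastic gradient descent
with Nesterov momentum 0.9, initial learning rate 0.01 decayed by 20%
every 5 epochs, batch size 128, no early stopping.  Cross-validation is
leave-one-subject-out: every 5-min segment of an hour-long epoch carries
that epoch's single expert grade, and subjects are never split across
train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .model import GRADES, CnnConfig, ThreeBranchCnn, build_model
from .tfd import TfdMatrix

__all__ = [
    "TrainConfig",
    "LabelledDataset",
    "lr_schedule",
    "loso_splits",
    "fit",
    "TfdCnnGrader",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser hyper-parameters (defaults are the published recipe)."""

    lr0: float = 0.01
    lr_decay: float = 0.8
    decay_every: int = 5
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 60
    decay_unit: str = "epochs"  # or "steps"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.decay_unit not in ("epochs", "steps"):
            raise ValueError("decay_unit must be 'epochs' or 'steps'")


@dataclass
class LabelledDataset:
    """TFD images with grade labels and provenance identifiers."""

    images: np.ndarray  # (n, height, width)
    grades: np.ndarray  # values in {1, 2, 3, 4}
    subjects: np.ndarray
    channels: np.ndarray | None = None
    segment_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.grades = np.asarray(self.grades, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, height, width)")
        n = self.images.shape[0]
        if self.grades.shape != (n,) or self.subjects.shape != (n,):
            raise ValueError("grades/subjects must align with images")
        if not np.all(np.isin(self.grades, GRADES)):
            raise ValueError("grades must be in {1, 2, 3, 4}")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, mask: np.ndarray) -> "LabelledDataset":
        pick = lambda a: None if a is None else np.asarray(a)[mask]
        return LabelledDataset(
            images=self.images[mask],
            grades=self.grades[mask],
            subjects=self.subjects[mask],
            channels=pick(self.channels),
            segment_indices=pick(self.segment_indices),
        )

    @classmethod
    def from_tfds(cls, items: Iterable[tuple[TfdMatrix, int, object]]) -> "LabelledDataset":
        """Build from (TfdMatrix, grade, subject_id) records."""
        imgs, grades, subjects, chans, segs = [], [], [], [], []
        for tfd, grade, subject in items:
            imgs.append(tfd.values)
            grades.append(grade)
            subjects.append(subject)
            chans.append(tfd.meta.get("channel", ""))
            segs.append(tfd.meta.get("segment_index", -1))
        return cls(
            images=np.stack(imgs),
            grades=np.array(grades),
            subjects=np.array(subjects),
            channels=np.array(chans),
            segment_indices=np.array(segs),
        )


def lr_schedule(epoch: int, cfg: TrainConfig | None = None) -> float:
    """lr0 * decay^floor(epoch / decay_every); piecewise constant."""
    cfg = cfg or TrainConfig()
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.decay_every)


def loso_splits(dataset: LabelledDataset):
    """One (train, test) mask pair per subject; subject-disjoint."""
    subjects = np.unique(dataset.subjects)
    if subjects.size < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    for subj in subjects:
        test = dataset.subjects == subj
        yield subj, ~test, test


def _onehot(grades: np.ndarray) -> np.ndarray:
    return np.eye(len(GRADES), dtype=np.float32)[np.asarray(grades) - 1]


def fit(
    model: ThreeBranchCnn,
    data: LabelledDataset,
    cfg: TrainConfig | None = None,
    log=None,
) -> dict[str, list[float]]:
    """SGD-Nesterov training loop; returns per-epoch loss/accuracy history."""
    cfg = cfg or TrainConfig()
    if len(data) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    velocity = [np.zeros_like(v) for _, v, _ in params]
    onehot = _onehot(data.grades)
    history: dict[str, list[float]] = {"loss": [], "accuracy": [], "lr": []}
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(data))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(data), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, y = data.images[idx], onehot[idx]
            lr = lr_schedule(
                epoch if cfg.decay_unit == "epochs" else step, cfg
            )
            logits = model.forward(x, training=True)
            probs = nn.softmax(logits)
            loss = nn.cross_entropy(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}, "
                    f"step {step}; reduce the learning rate"
                )
            model.backward((probs - y) / len(idx))
            for (name, value, grad), vel in zip(params, velocity):
                vel *= cfg.momentum
                vel += grad
                value -= lr * (grad + cfg.momentum * vel)
            losses.append(loss)
            hits += int((probs.argmax(axis=1) + 1 == data.grades[idx]).sum())
            seen += len(idx)
            step += 1
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(hits / seen)
        history["lr"].append(lr)
        if log is not None:
            log(
                f"epoch {epoch + 1}/{cfg.max_epochs} "
                f"loss {history['loss'][-1]:.4f} "
                f"acc {history['accuracy'][-1]:.3f} lr {lr:.5f}"
            )
    return history


class TfdCnnGrader(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper: grades TFD images with the three-branch CNN.

    Parameters mirror :class:`CnnConfig` and :class:`TrainConfig`; the
    fitted network is available as ``model_`` and the training history as
    ``history_``.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (256, 112),
        lr0: float = 0.01,
        lr_decay: float = 0.8,
        decay_every: int = 5,
        momentum: float = 0.9,
        batch_size: int = 128,
        max_epochs: int = 60,
        seed: int = 0,
    ):
        self.input_shape = input_shape
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.seed = seed

    def _dataset(self, X, y=None) -> LabelledDataset:
        X = np.asarray(X, dtype=np.float32)
        if y is None:
            y = np.ones(len(X), dtype=int)
        return LabelledDataset(
            images=X, grades=np.asarray(y, int), subjects=np.arange(len(X))
        )

    def fit(self, X, y, subjects: Sequence | None = None):
        data = self._dataset(X, y)
        if subjects is not None:
            data.subjects = np.asarray(subjects)
        self.classes_ = np.unique(np.asarray(y, int))
        self.model_ = build_model(
            CnnConfig(input_shape=tuple(self.input_shape), seed=self.seed)
        )
        self.history_ = fit(
            self.model_,
            data,
            TrainConfig(
                lr0=self.lr0,
                lr_decay=self.lr_decay,
                decay_every=self.decay_every,
                momentum=self.momentum,
                batch_size=self.batch_size,
                max_epochs=self.max_epochs,
                seed=self.seed,
            ),
        )
        return self

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = [
            self.model_.predict_proba(X[i : i + batch_size])
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out) if out else np.empty((0, len(GRADES)))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1) + 1
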