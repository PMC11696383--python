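"""Character recognition from per-character response profiles.

Two classifiers over the (mean amplitude, mean period) features:

* the threshold rule — a character is assigned to its own class when both
  its mean amplitude and mean period strictly exceed fixed thresholds, and
  is otherwise *rejected* (the published rule has no else-branch; rejects
  are tallied separately so the confusion matrix keeps its 26×26 shape);
* a nearest-profile classifier — assign the label of the reference profile
  closest in z-scored (amplitude, period) space, which makes the pipeline
  exercisable end-to-end on synthetic recordings.

Metrics: accuracy = Σ_i C_ii / (Σ_ij C_ij + Σ rejected); per-class precision
is the column ratio C_ii / Σ_j C_ji and recall the row ratio including the
class's rejects.  Undefined ratios (zero denominator) are returned as NaN,
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import LABELS, CharacterProfile, ProfileTable

__all__ = [
    "REJECT",
    "ConfusionMatrix",
    "threshold_classify",
    "build_confusion_matrix",
    "accuracy",
    "precision_recall",
    "NearestProfileClassifier",
    "nearest_profile_classify",
]

#: sentinel predicted label for characters clearing neither threshold
REJECT = "REJECT"


@dataclass
class ConfusionMatrix:
    """26×26 count matrix (rows: true class, columns: predicted) + reject tally."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((26, 26), dtype=int))
    rejected: np.ndarray = field(default_factory=lambda: np.zeros(26, dtype=int))
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.rejected = np.asarray(self.rejected, dtype=int)
        if self.counts.shape != (26, 26) or self.rejected.shape != (26,):
            raise ValueError("counts must be 26x26 and rejected length 26")
        if (self.counts < 0).any() or (self.rejected < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum() + self.rejected.sum())

    def update(self, true_label: str, predicted: str) -> None:
        i = _index(true_label)
        if predicted == REJECT:
            self.rejected[i] += 1
        else:
            self.counts[i, _index(predicted)] += 1


def _index(label: str) -> int:
    try:
        return LABELS.index(label)
    except ValueError:
        raise ValueError(f"label {label!r} outside A-Z") from None


def threshold_classify(
    profiles: ProfileTable, amplitude_threshold: float, period_threshold: float
) -> list[str]:
    """Apply the threshold rule to every character of a profile table.

    Returns, in alphabetical order, each character's own label when both its
    mean amplitude (mV) and mean period (s) strictly exceed the thresholds,
    else :data:`REJECT`.
    """
    out = []
    for p in profiles:
        hit = (p.amplitude.mean > amplitude_threshold) and (
            p.period.mean > period_threshold
        )
        out.append(p.label if hit else REJECT)
    return out


def build_confusion_matrix(
    true_labels: Sequence[str], predicted: Sequence[str]
) -> ConfusionMatrix:
    """Tally (true, predicted) pairs; ``REJECT`` predictions go to the reject tally."""
    if len(true_labels) != len(predicted):
        raise ValueError("true_labels and predicted must have equal length")
    cm = ConfusionMatrix()
    for y, yhat in zip(true_labels, predicted):
        cm.update(y, yhat)
    return cm


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified instances (rejects count as errors)."""
    total = cm.total
    if total == 0:
        raise ValueError("accuracy undefined for zero instances")
    return float(np.trace(cm.counts)) / total


def precision_recall(cm: ConfusionMatrix, label: str) -> tuple[float, float]:
    """(precision, recall) for one class; NaN where the denominator is zero."""
    i = _index(label)
    predicted_as_i = cm.counts[:, i].sum()
    true_i = cm.counts[i, :].sum() + cm.rejected[i]
    precision = cm.counts[i, i] / predicted_as_i if predicted_as_i else float("nan")
    recall = cm.counts[i, i] / true_i if true_i else float("nan")
    return float(precision), float(recall)


class NearestProfileClassifier:
    """Nearest-reference classifier in z-scored (mean amplitude, mean period).

    Follows the fit/predict protocol: :meth:`fit` stores the 26 reference
    feature vectors and their per-feature mean and sd (a zero sd disables the
    feature); :meth:`predict` assigns each observation the label of the
    nearest reference by Euclidean distance, breaking ties alphabetically.
    """

    def __init__(self) -> None:
        self.references_: Optional[np.ndarray] = None

    def fit(self, references: ProfileTable) -> "NearestProfileClassifier":
        feats = np.column_stack(
            [references.amplitude_means(), references.period_means()]
        )
        self.classes_ = np.array(references.labels)
        self.mean_ = feats.mean(axis=0)
        sd = feats.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, np.inf)  # constant feature -> no weight
        self.references_ = (feats - self.mean_) / self.scale_
        return self

    def predict_features(self, features: np.ndarray) -> np.ndarray:
        if self.references_ is None:
            raise RuntimeError("classifier is not fitted")
        z = (np.atleast_2d(features) - self.mean_) / self.scale_
        d = np.linalg.norm(z[:, None, :] - self.references_[None, :, :], axis=2)
        # argmin returns the first (alphabetically first) minimizer on ties
        return self.classes_[np.argmin(d, axis=1)]

    def predict(self, observed: Sequence[CharacterProfile]) -> np.ndarray:
        feats = np.array([[p.amplitude.mean, p.period.mean] for p in observed])
        return self.predict_features(feats)


def nearest_profile_classify(
    observed: CharacterProfile, references: ProfileTable
) -> str:
    """Label of the reference profile nearest to ``observed`` (z-scored space)."""
    clf = NearestProfileClassifier().fit(references)
    return str(clf.predict([observed])[0])
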