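"""Evaluation: confusion matrices, overall accuracy, repeated-trial
accuracy distributions, cross-subject transfer, and multi-session summaries.

A "trial" throughout is one windowed feature vector; overall accuracy is
the fraction of trials whose predicted posture equals the true posture.
Because bootstrap resampling makes forest accuracy a random variable, the
repeated-trials protocol re-splits, re-trains and re-tests many times and
summarises the resulting accuracy distribution by mean, quartiles and
Tukey outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from . import classify
from .postures import CLASS_ORDER, PostureLabel
from .wrist_features import LabeledDataset

logger = logging.getLogger(__name__)

Algorithm = Literal["rf", "svm"]

DEFAULT_SESSION_THRESHOLD = 0.82


@dataclass
class ConfusionMatrix:
    """Counts indexed (true class, predicted class) over the fixed order."""

    counts: np.ndarray  # (5, 5) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(CLASS_ORDER), len(CLASS_ORDER)):
            raise ValueError(f"confusion matrix must be {len(CLASS_ORDER)}x{len(CLASS_ORDER)}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_recall(self) -> dict[PostureLabel, float]:
        """Diagonal over row sum, for classes that occur in the truth."""
        out = {}
        for i, c in enumerate(CLASS_ORDER):
            row = self.counts[i].sum()
            if row > 0:
                out[c] = float(self.counts[i, i] / row)
        return out

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in CLASS_ORDER]
        return pd.DataFrame(self.counts, index=pd.Index(names, name="true"),
                            columns=pd.Index(names, name="predicted"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def confusion_matrix(
    truth: Sequence[PostureLabel], predicted: Sequence[PostureLabel]
) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into the fixed 5x5 grid."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(predicted)} predictions")
    labels = [c.value for c in CLASS_ORDER]
    counts = _sk_confusion_matrix(
        [t.value for t in truth], [p.value for p in predicted], labels=labels
    )
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correctly classified trials over total trials (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class AccuracyDistribution:
    """Per-trial accuracies with a box-plot style summary."""

    accuracies: np.ndarray
    resampled_splits: int = 0

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def q25(self) -> float:
        return float(np.percentile(self.accuracies, 25))

    @property
    def q75(self) -> float:
        return float(np.percentile(self.accuracies, 75))

    @property
    def outliers(self) -> np.ndarray:
        """Values beyond 1.5·IQR past the quartiles (Tukey's rule)."""
        iqr = self.q75 - self.q25
        lo, hi = self.q25 - 1.5 * iqr, self.q75 + 1.5 * iqr
        return self.accuracies[(self.accuracies < lo) | (self.accuracies > hi)]

    def summary(self) -> dict[str, float]:
        return {
            "n_trials": float(self.accuracies.size),
            "mean": self.mean,
            "q25": self.q25,
            "q75": self.q75,
            "n_outliers": float(self.outliers.size),
        }


def _fit_predict(
    train: LabeledDataset,
    test: LabeledDataset,
    algorithm: Algorithm,
    seed: int,
    C: float = classify.DEFAULT_C,
    gamma: float | None = None,
    n_trees: int = 30,
) -> list[PostureLabel]:
    if algorithm == "rf":
        model = classify.train_rf(train, n_trees=n_trees, seed=seed)
        return classify.predict_rf_batch(model, test.X)
    if algorithm == "svm":
        oaa = classify.train_oaa_svm(train, C=C, gamma=gamma)
        return classify.predict_oaa_batch(oaa, test.X)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def holdout_accuracy(
    dataset: LabeledDataset,
    algorithm: Algorithm,
    seed: int,
    train_fraction: float = 2 / 3,
    **hyper,
) -> float:
    """One seeded 2/3–1/3 split, train, test; returns overall accuracy."""
    train, test = classify.split_dataset(dataset, train_fraction, seed)
    pred = _fit_predict(train, test, algorithm, seed, **hyper)
    return overall_accuracy(confusion_matrix(test.labels, pred))


def repeated_trials(
    dataset: LabeledDataset,
    n_trials: int = 100,
    algorithm: Algorithm = "rf",
    base_seed: int = 0,
    train_fraction: float = 2 / 3,
    max_resample_attempts: int = 20,
    **hyper,
) -> AccuracyDistribution:
    """Repeat split/train/test ``n_trials`` times and collect accuracies.

    Trial t uses seed ``base_seed + t``, so a longer run is a prefix
    extension of a shorter one with the same base seed. A trial whose
    random split leaves the training or test side without one of the
    dataset's classes is redrawn (counted, and capped per trial).
    """
    classes = set(dataset.labels)
    accs = np.empty(n_trials)
    resampled = 0
    for t in range(n_trials):
        for attempt in range(max_resample_attempts):
            train, test = classify.split_dataset(
                dataset, train_fraction, [base_seed + t, attempt]
            )
            if set(train.labels) == classes and set(test.labels) == classes:
                break
            resampled += 1
        else:
            raise RuntimeError(
                f"trial {t}: no class-complete split in {max_resample_attempts} attempts"
            )
        pred = _fit_predict(train, test, algorithm, seed=base_seed + t, **hyper)
        accs[t] = overall_accuracy(confusion_matrix(test.labels, pred))
    if resampled:
        logger.info("repeated_trials redrew %d class-incomplete splits", resampled)
    return AccuracyDistribution(accuracies=accs, resampled_splits=resampled)


def cross_subject_eval(
    source: LabeledDataset,
    target: LabeledDataset,
    algorithm: Algorithm = "rf",
    seed: int = 0,
    **hyper,
) -> float:
    """Train on one subject's dataset, test on another's; overall accuracy."""
    if not (set(source.labels) & set(target.labels)):
        raise ValueError("source and target label sets are disjoint")
    pred = _fit_predict(source, target, algorithm, seed, **hyper)
    return overall_accuracy(confusion_matrix(target.labels, pred))


def session_summary(
    session_accuracies: Sequence[float],
    threshold: float = DEFAULT_SESSION_THRESHOLD,
) -> tuple[float, int]:
    """Mean session accuracy and the number of sessions strictly above
    the threshold (default 0.82)."""
    if len(session_accuracies) == 0:
        raise ValueError("no session accuracies given")
    accs = np.asarray(session_accuracies, dtype=np.float64)
    return float(accs.mean()), int(np.sum(accs > threshold))
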