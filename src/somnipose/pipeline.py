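"""End-to-end composition: streams in, trained model / posture labels out.

Training uses both sensors: the chest stream is calibrated on its upright
prefix and converted to per-window posture labels, the wrist stream is
reduced to per-frame mean features, the two are joined on the shared
window index, and a classifier is trained. Monitoring needs the wrist
stream only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chest_labeler, classify, wrist_features
from .io_streams import SensorStream
from .postures import PostureLabel

logger = logging.getLogger(__name__)

DEFAULT_CALIBRATION_MS = 5000


def calibration_reference(
    chest: SensorStream, reference_ms: int = DEFAULT_CALIBRATION_MS
) -> SensorStream:
    """The upright prefix of a chest stream used to estimate the mount angle."""
    keep = chest.timestamps_ms < reference_ms
    if not np.any(keep):
        raise chest_labeler.CalibrationError(
            f"no chest samples in the first {reference_ms} ms to calibrate on"
        )
    return SensorStream(
        site=chest.site,
        timestamps_ms=chest.timestamps_ms[keep],
        acc=chest.acc[keep],
        nominal_rate_hz=chest.nominal_rate_hz,
    )


@dataclass
class TrainingResult:
    model: classify.OaaSvmModel | classify.RfModel
    dataset: wrist_features.LabeledDataset
    rotation: chest_labeler.CalibrationRotation
    selected_trees: int | None  # None for SVM


def build_training_dataset(
    chest: SensorStream,
    wrist: SensorStream,
    windowsize_ms: int = 1000,
    calibration_ms: int = DEFAULT_CALIBRATION_MS,
    include_stand: bool = True,
) -> tuple[wrist_features.LabeledDataset, chest_labeler.CalibrationRotation]:
    """Chest labels joined with wrist features over the shared clock."""
    rotation = chest_labeler.compute_calibration(calibration_reference(chest, calibration_ms))
    labels = chest_labeler.label_stream(chest, rotation, windowsize_ms)
    feats = wrist_features.extract_features(wrist, windowsize_ms)
    dataset = wrist_features.build_dataset(feats, labels, include_stand=include_stand)
    return dataset, rotation


def train_from_streams(
    chest: SensorStream,
    wrist: SensorStream,
    algorithm: str = "rf",
    windowsize_ms: int = 1000,
    calibration_ms: int = DEFAULT_CALIBRATION_MS,
    include_stand: bool = True,
    C: float = classify.DEFAULT_C,
    gamma: float | None = None,
    max_trees: int = classify.DEFAULT_MAX_TREES,
    seed: int = 0,
) -> TrainingResult:
    """Full training pipeline on one paired session."""
    dataset, rotation = build_training_dataset(
        chest, wrist, windowsize_ms, calibration_ms, include_stand
    )
    selected: int | None = None
    if algorithm == "rf":
        # a purely random split can leave a rare class (often Stand, which
        # only covers the calibration prefix) out of the validation side;
        # retry with derived seeds until the split is class-complete
        last_exc: classify.TrainingError | None = None
        for attempt in range(20):
            try:
                selected = classify.select_tree_count(
                    dataset, max_trees=max_trees, seed=seed + 1009 * attempt
                )
                break
            except classify.TrainingError as exc:
                last_exc = exc
                logger.info("tree-count split attempt %d redrawn: %s", attempt, exc)
        else:
            raise classify.TrainingError(
                f"no class-complete validation split in 20 attempts: {last_exc}"
            )
        logger.info("selected %d trees by validation accuracy", selected)
        model: classify.OaaSvmModel | classify.RfModel = classify.train_rf(
            dataset, n_trees=selected, seed=seed
        )
    elif algorithm == "svm":
        model = classify.train_oaa_svm(dataset, C=C, gamma=gamma)
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return TrainingResult(model=model, dataset=dataset, rotation=rotation,
                          selected_trees=selected)


def monitor_stream(
    wrist: SensorStream,
    model: classify.OaaSvmModel | classify.RfModel,
    windowsize_ms: int = 1000,
) -> list[tuple[int, PostureLabel]]:
    """Wrist-only inference: one posture label per non-empty frame."""
    feats = wrist_features.extract_features(wrist, windowsize_ms)
    preds = classify.predict_batch(model, feats.values)
    return [(int(w), p) for w, p in zip(feats.frame_indices, preds)]
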