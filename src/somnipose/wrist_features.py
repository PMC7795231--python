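"""Wrist-stream segmentation, per-frame mean features, and dataset assembly.

The wrist stream is cut into non-overlapping frames of fixed duration
(default 1000 ms, half-open boundaries), each frame is reduced to its
per-axis arithmetic mean — the only features the classifier sees — and the
rows are joined on frame index with the posture labels produced
automatically from the chest sensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chest_labeler import _window_slices
from .io_streams import SensorStream
from .postures import PostureLabel

logger = logging.getLogger(__name__)

DEFAULT_WINDOWSIZE_MS = 1000


@dataclass(frozen=True)
class Frame:
    """A half-open time slice of a stream: windowsize·(i−1) ≤ t < windowsize·i."""

    frame_index: int  # 1-based
    timestamps_ms: np.ndarray
    acc: np.ndarray  # (n_i, 3)

    @property
    def n(self) -> int:
        return int(self.timestamps_ms.size)


@dataclass(frozen=True)
class FeatureVector:
    """Per-axis means (μx, μy, μz) of one frame, in G."""

    mu_x: float
    mu_y: float
    mu_z: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.mu_x, self.mu_y, self.mu_z])


@dataclass
class FeatureMatrix:
    """Ordered frame features: row i holds the means of frame ``frame_indices[i]``."""

    frame_indices: np.ndarray  # (N,), 1-based
    values: np.ndarray  # (N, 3) columns mu_x, mu_y, mu_z

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1, 3)
        if self.frame_indices.size != self.values.shape[0]:
            raise ValueError("frame_indices and values row count differ")

    def __len__(self) -> int:
        return int(self.frame_indices.size)


@dataclass
class LabeledDataset:
    """Feature rows paired one-to-one with posture labels."""

    features: FeatureMatrix
    labels: list[PostureLabel]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.features.values

    @property
    def y(self) -> np.ndarray:
        return np.array([lab.value for lab in self.labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.features.frame_indices,
                "mu_x": self.X[:, 0],
                "mu_y": self.X[:, 1],
                "mu_z": self.X[:, 2],
                "posture": [lab.value for lab in self.labels],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        df = pd.read_csv(path)
        feats = FeatureMatrix(
            frame_indices=df["frame_index"].to_numpy(),
            values=df[["mu_x", "mu_y", "mu_z"]].to_numpy(),
        )
        labels = [PostureLabel.from_string(s) for s in df["posture"]]
        return cls(features=feats, labels=labels)


def segment_frames(
    stream: SensorStream, windowsize_ms: int = DEFAULT_WINDOWSIZE_MS
) -> list[Frame]:
    """Partition a stream into half-open frames; empty frames are omitted.

    Omitted (gap) frames are logged. The last partial frame is kept as long
    as it contains at least one record.
    """
    if windowsize_ms <= 0:
        raise ValueError("windowsize_ms must be positive")
    frames = [
        Frame(w, stream.timestamps_ms[sl].copy(), stream.acc[sl].copy())
        for w, sl in _window_slices(stream.timestamps_ms, windowsize_ms)
    ]
    if frames:
        present = {f.frame_index for f in frames}
        gaps = sorted(set(range(1, frames[-1].frame_index + 1)) - present)
        if gaps:
            logger.warning("empty frames omitted: %s", gaps)
    return frames


def frame_mean(frame: Frame) -> FeatureVector:
    """Per-axis arithmetic mean of one frame's records."""
    if frame.n == 0:
        raise ValueError(f"frame {frame.frame_index} is empty")
    m = frame.acc.mean(axis=0)
    return FeatureVector(float(m[0]), float(m[1]), float(m[2]))


def feature_matrix(frames: Sequence[Frame]) -> FeatureMatrix:
    """Stack per-frame means into the design matrix, preserving frame order."""
    idx = np.array([f.frame_index for f in frames], dtype=np.int64)
    vals = (
        np.array([frame_mean(f).as_array for f in frames])
        if frames
        else np.empty((0, 3))
    )
    return FeatureMatrix(frame_indices=idx, values=vals)


def extract_features(
    stream: SensorStream, windowsize_ms: int = DEFAULT_WINDOWSIZE_MS
) -> FeatureMatrix:
    """Segment and reduce a wrist stream to its per-frame mean features."""
    return feature_matrix(segment_frames(stream, windowsize_ms))


def build_dataset(
    wrist_features: FeatureMatrix,
    chest_labels: Sequence[tuple[int, PostureLabel]],
    include_stand: bool = True,
) -> LabeledDataset:
    """Join wrist feature rows with chest labels on the shared window index.

    Both sides must have been computed with the same windowsize over a
    shared session clock. Rows present on only one side are dropped and
    counted in a log message. Stand windows are kept by default (upright is
    a legitimate fifth class); pass ``include_stand=False`` for a
    sleep-only model.

    Raises
    ------
    ValueError
        If no window index occurs on both sides.
    """
    label_map = dict(chest_labels)
    if len(label_map) != len(chest_labels):
        raise ValueError("duplicate window indices in chest labels")
    keep_rows: list[int] = []
    labels: list[PostureLabel] = []
    for row, w in enumerate(wrist_features.frame_indices):
        lab = label_map.get(int(w))
        if lab is None:
            continue
        if not include_stand and lab is PostureLabel.STAND:
            continue
        keep_rows.append(row)
        labels.append(lab)
    matched_windows = {int(wrist_features.frame_indices[r]) for r in keep_rows}
    dropped_features = len(wrist_features) - len(keep_rows)
    dropped_labels = sum(1 for w in label_map if w not in matched_windows)
    if dropped_features or dropped_labels:
        logger.info(
            "dataset join dropped %d unmatched feature rows and %d unmatched labels",
            dropped_features, dropped_labels,
        )
    if not keep_rows:
        raise ValueError("no overlapping windows between wrist features and chest labels")
    return LabeledDataset(
        features=FeatureMatrix(
            frame_indices=wrist_features.frame_indices[keep_rows],
            values=wrist_features.values[keep_rows],
        ),
        labels=labels,
    )
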