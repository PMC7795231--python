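"""Automatic posture labeling from the chest-worn accelerometer.

The chest sensor is strapped flat against the sternum, so the direction of
gravity in its frame encodes gross body orientation. The pipeline is:

1. *Calibration* — while the wearer stands or sits upright, estimate the
   in-plane mounting angle θ = atan2(ȳ, x̄) of the sensor and rotate the
   X–Y plane so that upright gravity lies along the calibrated X′ axis.
2. *Noise removal* — the prototype sensors occasionally emit spurious
   near-zero samples; within each sliding window, samples whose vector
   magnitude falls below the window variance of magnitudes are dropped.
3. *Window means* — per-axis arithmetic means over non-overlapping
   one-second windows.
4. *Posture decision* — the axis whose window mean has the largest absolute
   value dominates: X′ dominant means upright (Stand); Y′ dominant means
   side-lying (positive → left lateral, negative → right lateral); Z
   dominant means face-up (Supine) or face-down (Prone) by sign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io_streams import SensorStream
from .postures import PostureLabel

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = 1000


class CalibrationError(ValueError):
    """The calibration reference is degenerate (no in-plane gravity)."""


class LabelingError(ValueError):
    """The stream cannot be labeled (e.g. empty after cleaning)."""


@dataclass(frozen=True)
class CalibrationRotation:
    """Planar rotation of the sensor's X–Y axes by ``theta_rad``.

    Applying the rotation maps (x, y) to
    (x·cosθ + y·sinθ, −x·sinθ + y·cosθ); Z is untouched.
    """

    theta_rad: float

    def __post_init__(self) -> None:
        if not (-math.pi < self.theta_rad <= math.pi):
            raise ValueError(f"theta_rad {self.theta_rad} outside (-pi, pi]")


@dataclass(frozen=True)
class WindowFeature:
    """Per-axis means over one window. Indices are 1-based."""

    window_index: int
    mean_x: float
    mean_y: float
    mean_z: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.mean_x, self.mean_y, self.mean_z])


def compute_calibration(reference: SensorStream) -> CalibrationRotation:
    """Estimate the mounting angle from an upright reference interval.

    θ is the two-argument arctangent of the mean Y and mean X acceleration
    over the reference stream, so that rotating the reference mean yields
    y′ = 0 and x′ = √(x̄² + ȳ²).

    Raises
    ------
    CalibrationError
        If the reference mean has no X–Y component (sensor lying flat).
    """
    if len(reference) == 0:
        raise CalibrationError("empty calibration reference stream")
    mean_x = float(np.mean(reference.acc[:, 0]))
    mean_y = float(np.mean(reference.acc[:, 1]))
    if mean_x == 0.0 and mean_y == 0.0:
        raise CalibrationError(
            "degenerate calibration reference: mean X and Y are both zero"
        )
    theta = math.atan2(mean_y, mean_x)
    # atan2 returns [-pi, pi]; fold the -pi endpoint onto +pi.
    if theta == -math.pi:
        theta = math.pi
    return CalibrationRotation(theta_rad=theta)


def apply_calibration(rotation: CalibrationRotation, stream: SensorStream) -> SensorStream:
    """Rotate every sample's (x, y) by the calibration angle; Z unchanged."""
    c = math.cos(rotation.theta_rad)
    s = math.sin(rotation.theta_rad)
    acc = stream.acc.copy()
    x, y = acc[:, 0].copy(), acc[:, 1].copy()
    acc[:, 0] = x * c + y * s
    acc[:, 1] = -x * s + y * c
    return SensorStream(
        site=stream.site,
        timestamps_ms=stream.timestamps_ms.copy(),
        acc=acc,
        nominal_rate_hz=stream.nominal_rate_hz,
    )


def _window_slices(timestamps_ms: np.ndarray, window_ms: int) -> list[tuple[int, slice]]:
    """Half-open windows [k·w, (k+1)·w) as (1-based index, record slice).

    Windows with no records are omitted; the last partial window is kept.
    """
    if timestamps_ms.size == 0:
        return []
    idx = timestamps_ms // window_ms  # 0-based window of each record
    out: list[tuple[int, slice]] = []
    start = 0
    for k in range(len(idx)):
        if k + 1 == len(idx) or idx[k + 1] != idx[k]:
            out.append((int(idx[k]) + 1, slice(start, k + 1)))
            start = k + 1
    return out


def remove_noise(
    stream: SensorStream,
    window_ms: int = DEFAULT_WINDOW_MS,
    statistic: Literal["magnitude", "per_axis"] = "magnitude",
) -> SensorStream:
    """Drop spurious near-zero samples using a per-window variance threshold.

    Within each half-open window, the population variance v of the sample
    vector magnitudes is computed and used as a threshold: samples whose
    magnitude is strictly below v are removed. A constant window has v = 0,
    so nothing is ever removed from clean, steady data. With
    ``statistic="per_axis"`` the test is applied per axis instead
    (a sample is dropped if any |axis value| falls below that axis's
    window variance).

    May return an empty stream if every sample is glitched; callers must
    handle that case.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if len(stream) == 0:
        return stream
    keep = np.ones(len(stream), dtype=bool)
    if statistic == "magnitude":
        mags = stream.magnitudes
        for _, sl in _window_slices(stream.timestamps_ms, window_ms):
            v = float(np.var(mags[sl]))
            if v > 0.0:
                keep[sl] = mags[sl] >= v
    elif statistic == "per_axis":
        for _, sl in _window_slices(stream.timestamps_ms, window_ms):
            v = np.var(stream.acc[sl], axis=0)
            keep[sl] = np.all(np.abs(stream.acc[sl]) >= v, axis=1) | np.all(v == 0.0)
    else:
        raise ValueError(f"unknown noise statistic: {statistic!r}")
    return SensorStream(
        site=stream.site,
        timestamps_ms=stream.timestamps_ms[keep],
        acc=stream.acc[keep],
        nominal_rate_hz=stream.nominal_rate_hz,
    )


def window_means(stream: SensorStream, window_ms: int = DEFAULT_WINDOW_MS) -> list[WindowFeature]:
    """Per-axis means over non-overlapping half-open windows.

    A record at exactly t = k·window_ms belongs to window k+1 (1-based).
    Empty windows are omitted.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    feats = []
    for w, sl in _window_slices(stream.timestamps_ms, window_ms):
        m = stream.acc[sl].mean(axis=0)
        feats.append(WindowFeature(w, float(m[0]), float(m[1]), float(m[2])))
    return feats


def label_posture(feature: WindowFeature) -> PostureLabel:
    """Decide the posture of one calibrated window by dominant axis.

    The dominant axis is the argmax of |mean| over (X′, Y′, Z); exact
    dominance ties are broken by the fixed priority X′ > Y′ > Z with a
    warning (ties have measure zero on real data).
    """
    mags = (abs(feature.mean_x), abs(feature.mean_y), abs(feature.mean_z))
    best = max(mags)
    if sum(m == best for m in mags) > 1:
        logger.warning(
            "dominance tie in window %d (|means| = %r); priority X>Y'>Z applied",
            feature.window_index, mags,
        )
    dominant = mags.index(best)  # argmax honouring X > Y' > Z priority
    if dominant == 0:
        return PostureLabel.STAND
    if dominant == 1:
        return PostureLabel.LEFT_LATERAL if feature.mean_y > 0 else PostureLabel.RIGHT_LATERAL
    return PostureLabel.SUPINE if feature.mean_z > 0 else PostureLabel.PRONE


def label_stream(
    stream: SensorStream,
    rotation: CalibrationRotation,
    window_ms: int = DEFAULT_WINDOW_MS,
    noise_statistic: Literal["magnitude", "per_axis"] = "magnitude",
) -> list[tuple[int, PostureLabel]]:
    """Full chest pipeline: calibrate, clean, window, label.

    Returns one (window_index, label) pair per window that survives
    noise removal.

    Raises
    ------
    LabelingError
        If the stream is empty after noise removal.
    """
    calibrated = apply_calibration(rotation, stream)
    cleaned = remove_noise(calibrated, window_ms, statistic=noise_statistic)
    if len(cleaned) == 0:
        raise LabelingError("stream is empty after noise removal")
    return [(f.window_index, label_posture(f)) for f in window_means(cleaned, window_ms)]


def write_labels(labels: Sequence[tuple[int, PostureLabel]], path: str | Path) -> None:
    """Write labels as CSV with header ``window_index,posture``."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("window_index,posture\n")
        for w, lab in labels:
            fh.write(f"{w},{lab.value}\n")


def read_labels(path: str | Path) -> list[tuple[int, PostureLabel]]:
    """Read a ``window_index,posture`` CSV written by :func:`write_labels`."""
    out: list[tuple[int, PostureLabel]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "window_index,posture":
            raise ValueError(f"{path}: unexpected label CSV header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            w, p = line.strip().split(",")
            out.append((int(w), PostureLabel.from_string(p)))
    return out
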