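"""Synthetic paired chest/wrist accelerometer sessions with known posture truth.

The generative model is deliberately minimal, matching a means-only feature
pipeline: during each posture dwell the chest sensor sees the canonical
gravity direction for that posture (rotated by a fixed, unknown mounting
angle, which calibration must undo), and the wrist sensor sees a
posture-conditioned unit orientation. Both are corrupted by per-sample
Gaussian sensor noise; the wrist orientation additionally wanders slowly
around its posture mean with a configurable angular dispersion, re-drawn
once per second — so the wrist placement of any one analysis frame is an
independent draw from the posture's orientation distribution, emulating a
wearer who keeps adjusting the arm within a posture. Spurious near-zero
"glitch" samples are injected at a
configurable rate, and an ``overlap`` knob drags the prone wrist
orientation toward the right-lateral one — the mechanism by which prone
becomes the hardest posture to recognise from the wrist alone.

Every session starts with an upright (Stand) segment so that chest
calibration is always possible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .io_streams import SENSOR_RANGE_G, SensorStream
from .postures import CLASS_ORDER, PostureLabel

logger = logging.getLogger(__name__)

#: Gravity direction in the calibrated chest frame for each posture:
#: upright gravity lies on +X'; the lateral postures put it on ±Y';
#: supine/prone put it on ±Z.
CANONICAL_CHEST_GRAVITY: dict[PostureLabel, tuple[float, float, float]] = {
    PostureLabel.STAND: (1.0, 0.0, 0.0),
    PostureLabel.LEFT_LATERAL: (0.0, 1.0, 0.0),
    PostureLabel.RIGHT_LATERAL: (0.0, -1.0, 0.0),
    PostureLabel.SUPINE: (0.0, 0.0, 1.0),
    PostureLabel.PRONE: (0.0, 0.0, -1.0),
}

#: Default wrist orientations: pairwise at least 90 degrees apart, so the
#: separable profile is comfortably learnable from frame means.
DEFAULT_WRIST_MEANS: dict[PostureLabel, tuple[float, float, float]] = {
    PostureLabel.STAND: (0.0, 0.0, 1.0),
    PostureLabel.SUPINE: (0.0, 0.0, -1.0),
    PostureLabel.RIGHT_LATERAL: (0.0, 1.0, 0.0),
    PostureLabel.LEFT_LATERAL: (0.0, -1.0, 0.0),
    PostureLabel.PRONE: (1.0, 0.0, 0.0),
}

GLITCH_MAX_MAGNITUDE_G = 0.01


def canonical_chest_gravity(posture: PostureLabel) -> np.ndarray:
    """Unit gravity direction in the calibrated chest frame."""
    return np.array(CANONICAL_CHEST_GRAVITY[posture], dtype=np.float64)


@dataclass
class SimulationConfig:
    """Generative description of one synthetic two-sensor sleep session.

    Parameters
    ----------
    posture_sequence
        Ordered (posture, dwell seconds) segments. Sessions should begin
        with a Stand segment so chest calibration is possible.
    sample_rate_hz
        Nominal sampling rate of both sensors (default 60 Hz).
    noise_sd_g
        Per-axis Gaussian sensor noise standard deviation, in G.
    chest_mount_angle_rad
        In-plane rotation of the chest sensor as worn; ``None`` draws it
        uniformly from (−π, π] using the seed.
    wrist_orientation_means
        Unit wrist orientation per posture.
    wrist_orientation_sd
        Angular dispersion (radians) of the wrist orientation around its
        posture mean; the orientation is re-drawn once per second.
    overlap
        In [0, 1): mixes the prone wrist mean toward the right-lateral one,
        creating wrist-position overlap between the two postures.
    glitch_rate
        Per-sample probability of replacing a sample with a spurious
        near-zero artifact (magnitude < 0.01 G).
    seed
        Seeds all randomness; identical configs produce identical sessions.
    """

    posture_sequence: list[tuple[PostureLabel, float]]
    sample_rate_hz: float = 60.0
    noise_sd_g: float = 0.05
    chest_mount_angle_rad: float | None = None
    wrist_orientation_means: dict[PostureLabel, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WRIST_MEANS)
    )
    wrist_orientation_sd: float = 0.1
    overlap: float = 0.0
    glitch_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.posture_sequence:
            raise ValueError("posture_sequence must be non-empty")
        for posture, dwell in self.posture_sequence:
            if dwell <= 0:
                raise ValueError(f"dwell for {posture} must be positive, got {dwell}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0.0 <= self.glitch_rate <= 1.0:
            raise ValueError("glitch_rate must be in [0, 1]")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.noise_sd_g < 0 or self.wrist_orientation_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.chest_mount_angle_rad is not None and not (
            -math.pi < self.chest_mount_angle_rad <= math.pi
        ):
            raise ValueError("chest_mount_angle_rad must lie in (-pi, pi]")
        for posture, mean in self.wrist_orientation_means.items():
            norm = float(np.linalg.norm(mean))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(
                    f"wrist orientation mean for {posture} is not unit-norm ({norm:.6g})"
                )


@dataclass
class SimulatedSession:
    """A generated session: both streams plus per-window ground truth."""

    chest: SensorStream
    wrist: SensorStream
    truth: list[tuple[int, PostureLabel]]
    config: SimulationConfig
    mount_angle_rad: float


def _segment_table(
    sequence: Sequence[tuple[PostureLabel, float]]
) -> list[tuple[float, float, PostureLabel]]:
    """(start_ms, end_ms, posture) per segment."""
    out = []
    t = 0.0
    for posture, dwell_s in sequence:
        out.append((t, t + dwell_s * 1000.0, posture))
        t += dwell_s * 1000.0
    return out


def _window_truth(
    segments: list[tuple[float, float, PostureLabel]], window_ms: int = 1000
) -> list[tuple[int, PostureLabel]]:
    """Majority-dwell posture of every complete window."""
    total_ms = segments[-1][1]
    truth = []
    n_windows = int(total_ms // window_ms)
    for w in range(1, n_windows + 1):
        lo, hi = (w - 1) * window_ms, w * window_ms
        occupancy: dict[PostureLabel, float] = {}
        for s_lo, s_hi, posture in segments:
            ov = min(hi, s_hi) - max(lo, s_lo)
            if ov > 0:
                occupancy[posture] = occupancy.get(posture, 0.0) + ov
        winner = max(occupancy, key=lambda p: (occupancy[p], -CLASS_ORDER.index(p)))
        truth.append((w, winner))
    return truth


def _perturb_unit(mean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Re-draw a unit orientation around its mean with angular dispersion sd."""
    if sd == 0.0:
        return mean
    v = mean + rng.normal(0.0, sd, size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else mean


def simulate_session(config: SimulationConfig) -> SimulatedSession:
    """Generate one reproducible two-sensor session.

    Chest samples are the mount-angle-rotated canonical gravity plus
    Gaussian noise; wrist samples are once-per-second orientation draws
    plus Gaussian noise; glitches replace samples with near-zero artifacts.
    Noise and glitch injection use independent seeded streams, so a session
    with ``glitch_rate = 0`` differs from its glitchy twin only at the
    glitched samples. Emitted accelerations are clipped to the ±2 G sensor
    range (clipping is logged).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (seq_mount, seq_segment, seq_chest_noise, seq_wrist_noise,
     seq_chest_glitch, seq_wrist_glitch) = ss.spawn(6)
    rng_mount = np.random.default_rng(seq_mount)
    rng_segment = np.random.default_rng(seq_segment)

    if config.chest_mount_angle_rad is None:
        # uniform over (-pi, pi]
        mount = math.pi - float(rng_mount.uniform(0.0, 2.0 * math.pi))
    else:
        mount = config.chest_mount_angle_rad

    segments = _segment_table(config.posture_sequence)
    total_ms = segments[-1][1]
    dt_ms = 1000.0 / config.sample_rate_hz
    n_samples = int(math.ceil(total_ms / dt_ms))
    timestamps = np.round(np.arange(n_samples) * dt_ms).astype(np.int64)
    timestamps = timestamps[timestamps < total_ms]
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("sample_rate_hz too high for millisecond timestamps")
    n = timestamps.size

    # per-sample segment membership
    bounds = np.array([s[1] for s in segments])
    seg_idx = np.searchsorted(bounds, timestamps, side="right")

    # prone wrist mean dragged toward the right-lateral one
    wrist_means = {p: np.asarray(m, dtype=np.float64)
                   for p, m in config.wrist_orientation_means.items()}
    if config.overlap > 0.0:
        mixed = ((1.0 - config.overlap) * wrist_means[PostureLabel.PRONE]
                 + config.overlap * wrist_means[PostureLabel.RIGHT_LATERAL])
        wrist_means[PostureLabel.PRONE] = mixed / np.linalg.norm(mixed)

    # wrist orientation re-drawn once per second (and at posture changes):
    # each analysis frame sees an independent placement draw
    block = timestamps // 1000
    keys = block * (len(segments) + 1) + seg_idx
    wrist_base = np.empty((n, 3))
    start = 0
    for k in range(n):
        if k + 1 == n or keys[k + 1] != keys[k]:
            posture = segments[seg_idx[k]][2]
            wrist_base[start:k + 1] = _perturb_unit(
                wrist_means[posture], config.wrist_orientation_sd, rng_segment
            )
            start = k + 1

    c, s = math.cos(mount), math.sin(mount)
    chest_base = np.empty((n, 3))
    for k, (_, _, posture) in enumerate(segments):
        mask = seg_idx == k
        gx, gy, gz = CANONICAL_CHEST_GRAVITY[posture]
        # inverse of the calibration rotation: the sensor as worn
        chest_base[mask] = (gx * c - gy * s, gx * s + gy * c, gz)

    rng_cn = np.random.default_rng(seq_chest_noise)
    rng_wn = np.random.default_rng(seq_wrist_noise)
    chest_acc = chest_base + rng_cn.normal(0.0, config.noise_sd_g, size=(n, 3))
    wrist_acc = wrist_base + rng_wn.normal(0.0, config.noise_sd_g, size=(n, 3))

    for acc, seq in ((chest_acc, seq_chest_glitch), (wrist_acc, seq_wrist_glitch)):
        rng_g = np.random.default_rng(seq)
        mask = rng_g.random(n) < config.glitch_rate
        n_glitch = int(mask.sum())
        if n_glitch:
            direction = rng_g.normal(size=(n_glitch, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            magnitude = rng_g.uniform(0.0, GLITCH_MAX_MAGNITUDE_G / 2, size=(n_glitch, 1))
            acc[mask] = direction * magnitude

    for name, acc in (("chest", chest_acc), ("wrist", wrist_acc)):
        clipped = int(np.sum(np.abs(acc) > SENSOR_RANGE_G))
        if clipped:
            logger.warning("%s stream: %d component(s) clipped to ±%.0f G",
                           name, clipped, SENSOR_RANGE_G)
        np.clip(acc, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=acc)

    return SimulatedSession(
        chest=SensorStream("chest", timestamps.copy(), chest_acc,
                           nominal_rate_hz=config.sample_rate_hz),
        wrist=SensorStream("wrist", timestamps.copy(), wrist_acc,
                           nominal_rate_hz=config.sample_rate_hz),
        truth=_window_truth(segments),
        config=config,
        mount_angle_rad=mount,
    )


#: Dwell schedule shared by the default profiles: an upright calibration
#: prefix, then repeated visits to each lying posture (position changes,
#: as in a short supervised collection protocol). The confusable profile
#: doubles the right-lateral exposure, so that class has more training
#: data than prone.
_SEPARABLE_SEQUENCE: list[tuple[PostureLabel, float]] = [
    (PostureLabel.STAND, 5.0),
    (PostureLabel.SUPINE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
    (PostureLabel.LEFT_LATERAL, 15.0),
    (PostureLabel.PRONE, 15.0),
    (PostureLabel.SUPINE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
    (PostureLabel.LEFT_LATERAL, 15.0),
    (PostureLabel.PRONE, 15.0),
]

_CONFUSABLE_SEQUENCE: list[tuple[PostureLabel, float]] = [
    (PostureLabel.STAND, 5.0),
    (PostureLabel.SUPINE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
    (PostureLabel.LEFT_LATERAL, 15.0),
    (PostureLabel.PRONE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
    (PostureLabel.SUPINE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
    (PostureLabel.LEFT_LATERAL, 15.0),
    (PostureLabel.PRONE, 15.0),
    (PostureLabel.RIGHT_LATERAL, 15.0),
]


def default_config(
    profile: Literal["separable", "confusable"], seed: int = 0
) -> SimulationConfig:
    """Ready-made session profiles.

    ``separable``: wrist orientations pairwise at least 90° apart, no
    overlap, small arm-placement dispersion — every stage of the pipeline
    should succeed comfortably.

    ``confusable``: the prone wrist orientation is mixed 0.6 of the way
    toward the right-lateral one, arm-placement dispersion is large, and
    right-lateral segments are twice as frequent — the combination that
    makes prone the hardest class to recognise from the wrist.
    """
    if profile == "separable":
        return SimulationConfig(
            posture_sequence=list(_SEPARABLE_SEQUENCE),
            overlap=0.0,
            wrist_orientation_sd=0.1,
            seed=seed,
        )
    if profile == "confusable":
        return SimulationConfig(
            posture_sequence=list(_CONFUSABLE_SEQUENCE),
            overlap=0.6,
            wrist_orientation_sd=0.35,
            seed=seed,
        )
    raise ValueError(f"unknown profile: {profile!r}")
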