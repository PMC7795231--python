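"""Reading, validating and writing tri-axial accelerometer streams.

Two on-disk dialects are supported:

* the raw line dialect ``{<timestamp_ms>,<ax>}{<ay>,<az>}`` — one record per
  line, the format the sensing hardware emits; and
* plain CSV with header ``timestamp_ms,ax,ay,az``.

Acceleration values are in G and the sensor range is ±2 G. Timestamps are
integer milliseconds since session start and must be strictly increasing.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Hardware measurement range in G.
SENSOR_RANGE_G = 2.0

Site = Literal["chest", "wrist"]
Dialect = Literal["raw", "csv"]


class StreamParseError(ValueError):
    """A line or file could not be parsed as sensor data."""


class StreamValidationError(ValueError):
    """A stream violates its structural invariants."""


@dataclass(frozen=True)
class RawRecord:
    """One timestamped tri-axial acceleration sample."""

    timestamp_ms: int
    acc: tuple[float, float, float]

    @property
    def magnitude(self) -> float:
        ax, ay, az = self.acc
        return float(np.sqrt(ax * ax + ay * ay + az * az))


@dataclass
class SensorStream:
    """An ordered sequence of samples from one body site.

    Internally the samples are stored as numpy arrays: ``timestamps_ms``
    of shape ``(n,)`` (int64) and ``acc`` of shape ``(n, 3)`` (float64,
    columns X/Y/Z).
    """

    site: Site
    timestamps_ms: np.ndarray
    acc: np.ndarray
    nominal_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=np.float64))
        if self.timestamps_ms.size == 0:
            self.acc = self.acc.reshape(0, 3)
        if self.acc.shape != (self.timestamps_ms.size, 3):
            raise StreamValidationError(
                f"acc shape {self.acc.shape} does not match "
                f"{self.timestamps_ms.size} timestamps"
            )

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)

    @property
    def records(self) -> list[RawRecord]:
        return [
            RawRecord(int(t), (float(a[0]), float(a[1]), float(a[2])))
            for t, a in zip(self.timestamps_ms, self.acc)
        ]

    @classmethod
    def from_records(
        cls,
        site: Site,
        records: Sequence[RawRecord],
        nominal_rate_hz: float = 60.0,
    ) -> "SensorStream":
        ts = np.array([r.timestamp_ms for r in records], dtype=np.int64)
        acc = np.array([r.acc for r in records], dtype=np.float64).reshape(-1, 3)
        return cls(site=site, timestamps_ms=ts, acc=acc, nominal_rate_hz=nominal_rate_hz)

    @property
    def magnitudes(self) -> np.ndarray:
        """Euclidean norm of each sample, in G."""
        return np.linalg.norm(self.acc, axis=1)

    @property
    def duration_ms(self) -> int:
        return int(self.timestamps_ms[-1]) if len(self) else 0


@dataclass(frozen=True)
class Violation:
    """One validation finding: where it happened and what is wrong."""

    index: int
    kind: Literal["range", "ordering"]
    message: str


_RAW_LINE_RE = re.compile(
    r"^\s*\{\s*(?P<ts>[^,{}]+)\s*,\s*(?P<ax>[^,{}]+)\s*\}"
    r"\s*\{\s*(?P<ay>[^,{}]+)\s*,\s*(?P<az>[^,{}]+)\s*\}\s*$"
)


def parse_raw_line(line: str) -> RawRecord:
    """Parse one line of the raw dialect ``{timestamp,ax}{ay,az}``.

    The first brace group carries the timestamp and the X-axis value; the
    second group carries Y and Z. Internal whitespace is tolerated.

    Raises
    ------
    StreamParseError
        If the braces are malformed or a field is non-numeric.
    """
    m = _RAW_LINE_RE.match(line)
    if m is None:
        raise StreamParseError(f"malformed raw line: {line!r}")
    try:
        ts_raw = float(m.group("ts"))
        values = tuple(float(m.group(k)) for k in ("ax", "ay", "az"))
    except ValueError as exc:
        raise StreamParseError(f"non-numeric field in raw line: {line!r}") from exc
    ts = int(ts_raw)
    if ts_raw != ts:
        logger.warning("non-integer timestamp %r truncated to %d ms", ts_raw, ts)
    if ts < 0:
        raise StreamParseError(f"negative timestamp in raw line: {line!r}")
    return RawRecord(timestamp_ms=ts, acc=values)  # type: ignore[arg-type]


def format_raw_line(record: RawRecord) -> str:
    """Serialise a record back into the raw line dialect."""
    ax, ay, az = record.acc
    return f"{{{record.timestamp_ms},{ax:.17g}}}{{{ay:.17g},{az:.17g}}}"


def _check_monotone(timestamps: np.ndarray, path: str | Path | None = None) -> None:
    if timestamps.size >= 2:
        diffs = np.diff(timestamps)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            k = int(bad[0]) + 1
            where = f" in {path}" if path else ""
            raise StreamValidationError(
                f"non-monotone timestamp at record {k}{where}: "
                f"{int(timestamps[k])} ms does not follow {int(timestamps[k - 1])} ms"
            )


def read_stream(
    path: str | Path,
    site: Site,
    dialect: Dialect = "raw",
    nominal_rate_hz: float = 60.0,
) -> SensorStream:
    """Read a sensor stream from disk.

    Raises
    ------
    StreamParseError
        On malformed content or an unsupported dialect.
    StreamValidationError
        If the file is empty or timestamps are not strictly increasing.
    """
    path = Path(path)
    if dialect == "raw":
        records: list[RawRecord] = []
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(parse_raw_line(line))
                except StreamParseError as exc:
                    raise StreamParseError(f"{path}:{lineno}: {exc}") from exc
        stream = SensorStream.from_records(site, records, nominal_rate_hz)
    elif dialect == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            expected = ["timestamp_ms", "ax", "ay", "az"]
            if reader.fieldnames is None or list(reader.fieldnames) != expected:
                raise StreamParseError(
                    f"{path}: expected CSV header {','.join(expected)}, "
                    f"got {reader.fieldnames}"
                )
            ts_list: list[int] = []
            acc_list: list[tuple[float, float, float]] = []
            for lineno, row in enumerate(reader, start=2):
                try:
                    ts_raw = float(row["timestamp_ms"])
                    acc_list.append(
                        (float(row["ax"]), float(row["ay"]), float(row["az"]))
                    )
                except (TypeError, ValueError) as exc:
                    raise StreamParseError(f"{path}:{lineno}: non-numeric field") from exc
                ts = int(ts_raw)
                if ts_raw != ts:
                    logger.warning(
                        "%s:%d: non-integer timestamp %r truncated to %d ms",
                        path, lineno, ts_raw, ts,
                    )
                ts_list.append(ts)
        stream = SensorStream(
            site=site,
            timestamps_ms=np.array(ts_list, dtype=np.int64),
            acc=np.array(acc_list, dtype=np.float64).reshape(-1, 3),
            nominal_rate_hz=nominal_rate_hz,
        )
    else:
        raise StreamParseError(f"unsupported dialect: {dialect!r}")

    if len(stream) == 0:
        raise StreamValidationError(f"{path}: stream is empty")
    _check_monotone(stream.timestamps_ms, path)
    return stream


def write_stream(stream: SensorStream, path: str | Path, dialect: Dialect = "raw") -> None:
    """Write a stream to disk in the requested dialect."""
    path = Path(path)
    if dialect == "raw":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for record in stream.records:
                fh.write(format_raw_line(record) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp_ms", "ax", "ay", "az"])
            for t, (ax, ay, az) in zip(stream.timestamps_ms, stream.acc):
                writer.writerow([int(t), f"{ax:.17g}", f"{ay:.17g}", f"{az:.17g}"])
    else:
        raise StreamParseError(f"unsupported dialect: {dialect!r}")


def validate_stream(stream: SensorStream) -> list[Violation]:
    """Report range and ordering violations without mutating the stream.

    Each acceleration component must lie within the ±2 G sensor range and
    timestamps must be strictly increasing.
    """
    violations: list[Violation] = []
    axes = "xyz"
    out = np.abs(stream.acc) > SENSOR_RANGE_G
    for i, j in zip(*np.nonzero(out)):
        violations.append(
            Violation(
                index=int(i),
                kind="range",
                message=(
                    f"record {int(i)}: axis {axes[int(j)]} value "
                    f"{stream.acc[i, j]:.6g} G outside ±{SENSOR_RANGE_G} G"
                ),
            )
        )
    if len(stream) >= 2:
        diffs = np.diff(stream.timestamps_ms)
        for k in np.nonzero(diffs <= 0)[0]:
            i = int(k) + 1
            violations.append(
                Violation(
                    index=i,
                    kind="ordering",
                    message=(
                        f"record {i}: timestamp {int(stream.timestamps_ms[i])} ms "
                        f"does not increase past {int(stream.timestamps_ms[i - 1])} ms"
                    ),
                )
            )
    return violations
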