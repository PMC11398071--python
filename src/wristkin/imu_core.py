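"""Core IMU domain types, session I/O and multi-sensor synchronization.

Three body-mounted sensors (S1 at the wrist rotation axis, S2 on the hand
segment, S3 on the forearm segment) each stream time-stamped tri-axial
accelerometer (m/s^2) and gyroscope (deg/s) readings at a nominal 50 Hz.
Sensors are polled round-robin by the receiver, which stamps every reading;
timestamps are therefore authoritative and never re-derived from sample
index.  Synchronization places all three streams on a common arithmetic
time grid by nearest-neighbour matching with a bounded skew.

Sessions are serialized as plain CSV with the header
``sensor_id,t,ax,ay,az,gx,gy,gz`` (units: seconds, m/s^2, deg/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # placement typing only; avoids an import cycle
    from .kinematics import ArmModel

__all__ = [
    "SENSOR_IDS",
    "WristkinError",
    "ParseError",
    "ValidationError",
    "StructuralError",
    "SyncError",
    "ImuSample",
    "ImuStream",
    "SyncedFrame",
    "SyncResult",
    "SessionRecording",
    "parse_sensor_line",
    "read_session",
    "write_session",
    "round_robin_sync",
]

SENSOR_IDS = ("S1", "S2", "S3")

SESSION_HEADER = "sensor_id,t,ax,ay,az,gx,gy,gz"


class WristkinError(Exception):
    """Base class for all package errors."""


class ParseError(WristkinError):
    """Malformed input text (wrong field count, unreadable number)."""


class ValidationError(WristkinError):
    """Well-formed input violating a domain invariant."""


class StructuralError(WristkinError):
    """A file or session missing required structure (streams, header)."""


class SyncError(WristkinError):
    """Streams cannot be placed on a common grid."""


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite values: {a}")
    return a


@dataclass(frozen=True)
class ImuSample:
    """One sensor reading: timestamp, specific force and angular rate.

    ``accel`` is the raw accelerometer output in the sensor frame (m/s^2,
    gravity included -- a level, static sensor reads (0, 0, +9.81));
    ``gyro`` is the angular rate in deg/s about the sensor axes.
    """

    sensor_id: str
    t: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_id not in SENSOR_IDS:
            raise ValidationError(
                f"unknown sensor_id {self.sensor_id!r}; expected one of {SENSOR_IDS}"
            )
        if not (math.isfinite(self.t) and self.t >= 0.0):
            raise ValidationError(f"timestamp must be finite and >= 0, got {self.t}")
        object.__setattr__(self, "accel", _as_vec3(self.accel, "accel"))
        object.__setattr__(self, "gyro", _as_vec3(self.gyro, "gyro"))


class ImuStream:
    """Time-ordered samples of a single sensor, stored as dense arrays.

    Invariants: strictly increasing timestamps, one sensor_id, positive
    nominal rate.
    """

    def __init__(
        self,
        sensor_id: str,
        t: np.ndarray,
        accel: np.ndarray,
        gyro: np.ndarray,
        nominal_rate: float = 50.0,
    ) -> None:
        if sensor_id not in SENSOR_IDS:
            raise ValidationError(f"unknown sensor_id {sensor_id!r}")
        if nominal_rate <= 0:
            raise ValidationError("nominal_rate must be > 0")
        t = np.asarray(t, dtype=float)
        accel = np.asarray(accel, dtype=float)
        gyro = np.asarray(gyro, dtype=float)
        n = t.shape[0]
        if t.ndim != 1 or accel.shape != (n, 3) or gyro.shape != (n, 3):
            raise ValidationError(
                f"shape mismatch: t {t.shape}, accel {accel.shape}, gyro {gyro.shape}"
            )
        if n == 0:
            raise ValidationError("stream must contain at least one sample")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(accel)) and np.all(np.isfinite(gyro))):
            raise ValidationError("stream contains non-finite values")
        if t[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        if n > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(f"timestamps of {sensor_id} not strictly increasing")
        self.sensor_id = sensor_id
        self.t = t
        self.accel = accel
        self.gyro = gyro
        self.nominal_rate = float(nominal_rate)

    @classmethod
    def from_samples(
        cls, samples: Sequence[ImuSample], nominal_rate: float = 50.0
    ) -> "ImuStream":
        if not samples:
            raise ValidationError("cannot build a stream from zero samples")
        sid = samples[0].sensor_id
        if any(s.sensor_id != sid for s in samples):
            raise ValidationError("all samples of a stream must share sensor_id")
        return cls(
            sid,
            np.array([s.t for s in samples]),
            np.stack([s.accel for s in samples]),
            np.stack([s.gyro for s in samples]),
            nominal_rate,
        )

    def __len__(self) -> int:
        return self.t.shape[0]

    def sample(self, i: int) -> ImuSample:
        return ImuSample(self.sensor_id, float(self.t[i]), self.accel[i], self.gyro[i])

    def __iter__(self) -> Iterator[ImuSample]:
        return (self.sample(i) for i in range(len(self)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class SyncedFrame:
    """One instant on the common grid with the nearest sample of each sensor."""

    t: float
    sample_by_sensor: Mapping[str, ImuSample]

    def __post_init__(self) -> None:
        if set(self.sample_by_sensor) != set(SENSOR_IDS):
            raise ValidationError(
                f"frame must hold exactly one sample per sensor {SENSOR_IDS}"
            )


@dataclass
class SyncResult:
    """Output of :func:`round_robin_sync`: kept frames plus the drop count."""

    frames: list[SyncedFrame]
    n_dropped: int
    rate: float

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SyncedFrame]:
        return iter(self.frames)

    def stream(self, sensor_id: str) -> ImuStream:
        """Re-express one sensor's matched samples on the common grid."""
        t = np.array([f.t for f in self.frames])
        accel = np.stack([f.sample_by_sensor[sensor_id].accel for f in self.frames])
        gyro = np.stack([f.sample_by_sensor[sensor_id].gyro for f in self.frames])
        return ImuStream(sensor_id, t, accel, gyro, self.rate)


@dataclass
class SessionRecording:
    """A full three-sensor recording plus placement and labels."""

    streams: dict[str, ImuStream]
    placement: "ArmModel | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(self.streams)
        if ids != sorted(SENSOR_IDS):
            raise StructuralError(
                f"session must contain exactly the streams {SENSOR_IDS}, got {ids}"
            )
        for sid, stream in self.streams.items():
            if stream.sensor_id != sid:
                raise ValidationError(f"stream keyed {sid} has sensor_id {stream.sensor_id}")


def parse_sensor_line(line: str, line_number: int | None = None) -> ImuSample:
    """Parse one ``sensor_id,t,ax,ay,az,gx,gy,gz`` CSV line into an ImuSample.

    Raises :class:`ParseError` (naming the line number when given) for a
    wrong field count or unreadable number, :class:`ValidationError` for
    non-finite values or an unknown sensor id.
    """
    where = "" if line_number is None else f" (line {line_number})"
    fields = line.strip().split(",")
    if len(fields) != 8:
        raise ParseError(f"expected 8 comma-separated fields, got {len(fields)}{where}")
    sid = fields[0].strip()
    try:
        values = [float(x) for x in fields[1:]]
    except ValueError as exc:
        raise ParseError(f"unreadable numeric field{where}: {exc}") from exc
    try:
        return ImuSample(sid, values[0], values[1:4], values[4:7])
    except ValidationError as exc:
        raise ValidationError(f"{exc}{where}") from exc


def read_session(path) -> SessionRecording:
    """Read a session CSV (see module docstring for the dialect).

    The header row is mandatory.  Raises :class:`StructuralError` for an
    empty file, a bad header, or a missing sensor stream.
    """
    samples: dict[str, list[ImuSample]] = {sid: [] for sid in SENSOR_IDS}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise StructuralError(f"{path}: empty file")
        if header.strip() != SESSION_HEADER:
            raise StructuralError(
                f"{path}: bad header {header.strip()!r}; expected {SESSION_HEADER!r}"
            )
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            sample = parse_sensor_line(line, line_number=i)
            samples[sample.sensor_id].append(sample)
    missing = [sid for sid in SENSOR_IDS if not samples[sid]]
    if missing:
        raise StructuralError(f"{path}: missing stream(s) {missing}")
    streams = {sid: ImuStream.from_samples(samples[sid]) for sid in SENSOR_IDS}
    return SessionRecording(streams=streams)


def write_session(session: SessionRecording, path) -> None:
    """Write a session CSV; numbers use shortest round-trip representation,
    so ``read_session(write_session(s))`` is the identity on valid sessions."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SESSION_HEADER + "\n")
        for sid in SENSOR_IDS:
            stream = session.streams[sid]
            for i in range(len(stream)):
                nums = [stream.t[i], *stream.accel[i], *stream.gyro[i]]
                fh.write(sid + "," + ",".join(repr(float(x)) for x in nums) + "\n")


def round_robin_sync(
    streams: Iterable[ImuStream],
    rate: float = 50.0,
    max_skew: float | None = None,
) -> SyncResult:
    """Place three sensor streams on a common grid of step 1/rate.

    The grid spans the overlap of the three streams; each frame holds the
    nearest sample of each sensor.  Frames where any sensor's nearest
    sample is further than ``max_skew`` (default half a polling cycle,
    0.5/rate) are dropped and counted.  Order of the input streams is
    irrelevant.
    """
    streams = list(streams)
    ids = sorted(s.sensor_id for s in streams)
    if ids != sorted(SENSOR_IDS):
        raise SyncError(f"need exactly the streams {SENSOR_IDS}, got {ids}")
    if rate <= 0:
        raise SyncError("rate must be > 0")
    if max_skew is None:
        max_skew = 0.5 / rate
    by_id = {s.sensor_id: s for s in streams}

    start = max(s.t[0] for s in streams)
    end = min(s.t[-1] for s in streams)
    if end < start:
        raise SyncError("streams have no common time interval")
    # grid as an exact arithmetic progression: start + k/rate
    n = int(math.floor((end - start) * rate + 1e-9)) + 1
    grid = start + np.arange(n) / rate
    if n < 2:
        raise SyncError(f"overlap supports only {n} frame(s); need at least 2")

    nearest: dict[str, np.ndarray] = {}
    skew_ok = np.ones(n, dtype=bool)
    for sid in SENSOR_IDS:
        s = by_id[sid]
        idx = np.searchsorted(s.t, grid)
        idx = np.clip(idx, 1, len(s) - 1) if len(s) > 1 else np.zeros(n, dtype=int)
        left = idx - 1
        choose_left = np.abs(grid - s.t[left]) <= np.abs(s.t[idx] - grid)
        idx = np.where(choose_left, left, idx)
        nearest[sid] = idx
        skew_ok &= np.abs(s.t[idx] - grid) <= max_skew + 1e-12

    frames: list[SyncedFrame] = []
    for k in range(n):
        if not skew_ok[k]:
            continue
        frames.append(
            SyncedFrame(
                t=float(grid[k]),
                sample_by_sensor={
                    sid: by_id[sid].sample(int(nearest[sid][k])) for sid in SENSOR_IDS
                },
            )
        )
    n_dropped = int(n - len(frames))
    if len(frames) < 2:
        raise SyncError("fewer than 2 frames survive skew filtering")
    return SyncResult(frames=frames, n_dropped=n_dropped, rate=float(rate))
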