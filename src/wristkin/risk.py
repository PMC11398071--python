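"""Ergonomic risk banding and cut-event detection.

Wrist angles are classified into three bands on absolute value, following
the simplified RULA-style thresholds used for vineyard pruning work:

* low (acceptable posture):      |angle| in [0, 20] degrees
* medium (monitor the worker):   |angle| in (20, 45] degrees
* high (unacceptable risk):      |angle| > 45 degrees

The 45-degree boundary is exclusive on the high side: 45.00 counts medium.
Frequencies are reported as truncated integer percentages (floor of
100*count/n) per axis and pooled over all axes.

Cut events are localized on the hand-sensor acceleration trace: bursts of
| ||a|| - g | above a threshold, merged within a minimum gap and extended
outward to a low onset floor, replace the manual graphical reading of the
acceleration plots.  Within each event window the representative posture
per axis is the signed angle of maximal absolute value (worst posture, as
RULA scores it).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .fusion import GRAVITY
from .imu_core import ImuStream, ValidationError
from .kinematics import JointAngleSeries

__all__ = [
    "AXES",
    "RiskLevel",
    "RiskThresholds",
    "CutEvent",
    "RiskReport",
    "classify_angle",
    "detect_cut_windows",
    "representative_angle",
    "risk_frequency_table",
    "load_pruning_fixture",
]

AXES = ("X", "Y", "Z")


class RiskLevel(enum.IntEnum):
    """Ordered three-band risk level (green / yellow / red)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class RiskThresholds:
    """Band edges in degrees: low is [0, low_max], medium (low_max, med_max],
    high above."""

    low_max: float = 20.0
    med_max: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_max < self.med_max:
            raise ValidationError(
                f"need 0 < low_max < med_max, got ({self.low_max}, {self.med_max})"
            )


def classify_angle(angle_deg: float, thresholds: RiskThresholds | None = None) -> RiskLevel:
    """Band of one wrist angle; classification is on |angle|."""
    th = thresholds or RiskThresholds()
    if not math.isfinite(angle_deg):
        raise ValidationError(f"angle must be finite, got {angle_deg}")
    a = abs(angle_deg)
    if a <= th.low_max:
        return RiskLevel.LOW
    if a <= th.med_max:
        return RiskLevel.MEDIUM
    return RiskLevel.HIGH


@dataclass(frozen=True)
class CutEvent:
    """One detected (or programmed) cut: a time window, optionally with the
    representative wrist angles per axis."""

    start: float
    end: float
    peak_angles: np.ndarray | None = None  # (3,) degrees, X/Y/Z

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"need start < end, got [{self.start}, {self.end}]")

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_cut_windows(
    stream: ImuStream,
    threshold: float = 2.0,
    min_gap: float = 0.5,
    expected_count: int | None = None,
    onset_floor: float = 0.15,
    gravity_mag: float = GRAVITY,
) -> list[CutEvent]:
    """Locate cut bursts on an acceleration trace (normally the S2 hand sensor).

    The excess signal e(t) = | ||a(t)|| - g | is thresholded; contiguous
    super-threshold regions closer than ``min_gap`` seconds are merged, and
    every region is extended outward while e stays above ``onset_floor`` so
    the reported onset tracks the true burst start rather than the
    threshold crossing.  With ``expected_count``, the strongest k bursts
    are returned in time order; fewer available bursts raise a warning and
    return the partial result.
    """
    if stream.duration <= min_gap:
        raise ValidationError("stream shorter than min_gap")
    excess = np.abs(np.linalg.norm(stream.accel, axis=1) - gravity_mag)
    above = excess > threshold
    if not above.any():
        if expected_count:
            warnings.warn(
                f"expected {expected_count} cut bursts, found 0", stacklevel=2
            )
        return []

    # contiguous super-threshold regions as (start_idx, end_idx) inclusive
    starts = list(np.flatnonzero(above & ~np.roll(above, 1)))
    if above[0]:
        starts = [0] + [s for s in starts if s != 0]
    ends = list(np.flatnonzero(above & ~np.roll(above, -1)))
    if above[-1] and (len(ends) == 0 or ends[-1] != len(above) - 1):
        ends.append(len(above) - 1)
    regions = list(zip(starts, ends))

    merged: list[list[int]] = []
    for s, e in regions:
        if merged and stream.t[s] - stream.t[merged[-1][1]] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[tuple[float, CutEvent]] = []
    n = len(stream)
    for s, e in merged:
        while s > 0 and excess[s - 1] > onset_floor:
            s -= 1
        while e < n - 1 and excess[e + 1] > onset_floor:
            e += 1
        # refine the edges to sub-sample precision: a smooth burst leaves
        # zero quadratically, so sqrt(excess) is locally linear on the
        # flank -- extrapolate it to zero (clipped to two samples out)
        start = float(stream.t[s])
        if 0 < s < n - 1:
            r0, r1 = math.sqrt(excess[s]), math.sqrt(excess[s + 1])
            if r1 > r0:
                dt = float(stream.t[s + 1] - stream.t[s])
                start = max(start - r0 * dt / (r1 - r0), float(stream.t[max(s - 2, 0)]))
        end = float(stream.t[e])
        if 0 < e < n - 1:
            r0, r1 = math.sqrt(excess[e]), math.sqrt(excess[e - 1])
            if r1 > r0:
                dt = float(stream.t[e] - stream.t[e - 1])
                end = min(end + r0 * dt / (r1 - r0), float(stream.t[min(e + 2, n - 1)]))
        strength = float(excess[s : e + 1].max())
        events.append((strength, CutEvent(start, end)))

    if expected_count is not None:
        if len(events) < expected_count:
            warnings.warn(
                f"expected {expected_count} cut bursts, found {len(events)}",
                stacklevel=2,
            )
        else:
            events = sorted(events, key=lambda se: -se[0])[:expected_count]
    return [ev for _, ev in sorted(events, key=lambda se: se[1].start)]


def representative_angle(
    angles: JointAngleSeries, window: CutEvent
) -> np.ndarray:
    """Signed per-axis angle of maximal absolute value inside the window
    (the worst posture reached during the cut)."""
    mask = (angles.t >= window.start - 1e-12) & (angles.t <= window.end + 1e-12)
    if not mask.any():
        raise ValidationError(
            f"window [{window.start}, {window.end}] contains no angle samples"
        )
    seg = angles.euler[mask]
    idx = np.argmax(np.abs(seg), axis=0)
    return seg[idx, np.arange(3)]


@dataclass
class RiskReport:
    """Risk-band frequencies per axis and pooled over all axes.

    ``counts[axis][level]`` are raw occurrence counts; ``percent`` holds
    truncated integer percentages, floor(100*count/n) -- the reporting
    convention of the field study this mirrors.  Counts per axis always
    sum to that axis's n.
    """

    counts: dict[str, dict[RiskLevel, int]]
    n: dict[str, int]
    thresholds: RiskThresholds

    @property
    def percent(self) -> dict[str, dict[RiskLevel, int]]:
        return {
            axis: {
                lev: (100 * c) // self.n[axis] for lev, c in by_level.items()
            }
            for axis, by_level in self.counts.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Table-style view: one row per band (high first), integer percent
        per axis column plus the pooled "All" column."""
        th = self.thresholds
        bands = {
            RiskLevel.HIGH: f">{th.med_max:g}",
            RiskLevel.MEDIUM: f"{th.low_max:g}-{th.med_max:g}",
            RiskLevel.LOW: f"0-{th.low_max:g}",
        }
        pct = self.percent
        rows = []
        for lev in (RiskLevel.HIGH, RiskLevel.MEDIUM, RiskLevel.LOW):
            rows.append(
                {
                    "level": lev.label,
                    "band_deg": bands[lev],
                    **{axis: pct[axis][lev] for axis in (*AXES, "All")},
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "thresholds": {"low_max": self.thresholds.low_max, "med_max": self.thresholds.med_max},
            "n": dict(self.n),
            "counts": {
                axis: {lev.label: c for lev, c in by_level.items()}
                for axis, by_level in self.counts.items()
            },
            "percent": {
                axis: {lev.label: p for lev, p in by_level.items()}
                for axis, by_level in self.percent.items()
            },
        }


def risk_frequency_table(
    records: "Iterable[tuple[str, float]] | pd.DataFrame",
    thresholds: RiskThresholds | None = None,
) -> RiskReport:
    """Band counts and truncated percentages from (axis, angle) records.

    ``records`` is any iterable of (axis, angle_deg) pairs or a DataFrame
    with ``axis`` and ``angle_deg`` columns.  The pooled "All" column uses
    every record.
    """
    th = thresholds or RiskThresholds()
    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["axis"], records["angle_deg"]))
    else:
        pairs = list(records)
    if not pairs:
        raise ValidationError("no angle records to classify")
    counts = {axis: {lev: 0 for lev in RiskLevel} for axis in (*AXES, "All")}
    n = {axis: 0 for axis in (*AXES, "All")}
    for axis, angle in pairs:
        axis = str(axis).upper()
        if axis not in AXES:
            raise ValidationError(f"unknown axis {axis!r}; expected one of {AXES}")
        lev = classify_angle(float(angle), th)
        counts[axis][lev] += 1
        counts["All"][lev] += 1
        n[axis] += 1
        n["All"] += 1
    counts = {axis: by for axis, by in counts.items() if n[axis] > 0 or axis == "All"}
    n = {axis: c for axis, c in n.items() if axis in counts}
    return RiskReport(counts=counts, n=n, thresholds=th)


def load_pruning_fixture() -> pd.DataFrame:
    """The printed field-trial wrist angles: 4 operators x 3 sequences x
    7 cuts x 3 axes = 252 records, columns
    ``operator,sequence,cut,axis,angle_deg``."""
    with resources.files("wristkin.data").joinpath("pruning_angles.csv").open("r") as fh:
        return pd.read_csv(fh)
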