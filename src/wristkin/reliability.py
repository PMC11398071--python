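"""Reference-angle validation statistics.

In the bench protocol, four operators reproduced reference wrist angles of
15, 45 and 60 degrees about each axis, three repetitions each, against a
goniometer-verified template; the 108 measured angles are shipped as a
fixture.  :func:`summarize` condenses them into per-(angle, axis) cells of
mean +/- sample standard deviation (n-1 denominator), plus a pooled "All"
column that aggregates the raw values of the three axes.

Reported values are rounded to 2 decimals (round-half-even) at the output
boundary only; internal values keep full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imu_core import ValidationError
from .risk import AXES

__all__ = [
    "REFERENCE_ANGLES",
    "ReferenceTrial",
    "SummaryCell",
    "SummaryTable",
    "round2",
    "summarize",
    "load_reference_fixture",
    "mixed_model_fit",
]

REFERENCE_ANGLES = (15.0, 45.0, 60.0)


def round2(x: float) -> float:
    """Round to 2 decimals with ties to even, applied to the shortest
    decimal representation of x (so 0.125 -> 0.12, not a binary artefact)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ReferenceTrial:
    """One bench measurement: operator 1-4, axis X/Y/Z, reference angle in
    {15, 45, 60} degrees, repetition 1-3, and the angle the sensors read."""

    operator: int
    axis: str
    reference_angle: float
    repetition: int
    measured_angle: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValidationError(f"axis must be one of {AXES}, got {self.axis!r}")
        if float(self.reference_angle) not in REFERENCE_ANGLES:
            raise ValidationError(
                f"reference_angle must be one of {REFERENCE_ANGLES}, got {self.reference_angle}"
            )
        if not np.isfinite(self.measured_angle):
            raise ValidationError("measured_angle must be finite")


@dataclass(frozen=True)
class SummaryCell:
    """Mean +/- sample SD of one (reference angle, axis) cell."""

    mean: float
    sd: float | None  # None when n < 2
    n: int


@dataclass
class SummaryTable:
    """Per-(reference angle x axis) summary cells plus the pooled "All"
    column (raw values of all three axes aggregated)."""

    cells: dict[tuple[float, str], SummaryCell]

    def cell(self, reference_angle: float, axis: str) -> SummaryCell:
        return self.cells[(float(reference_angle), axis)]

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        """One row per reference angle, ``<axis>_mean`` / ``<axis>_sd`` /
        ``<axis>_n`` columns; values rounded half-even unless decimals=None."""
        fmt = (lambda v: v) if decimals is None else (lambda v: None if v is None else round2(v))
        rows = []
        for angle in sorted({a for a, _ in self.cells}):
            row: dict = {"reference_angle": angle}
            for axis in (*AXES, "All"):
                if (angle, axis) not in self.cells:
                    continue
                c = self.cells[(angle, axis)]
                row[f"{axis}_mean"] = fmt(c.mean)
                row[f"{axis}_sd"] = fmt(c.sd)
                row[f"{axis}_n"] = c.n
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(trials: Iterable[ReferenceTrial]) -> SummaryTable:
    """Arithmetic mean and sample SD (n-1) per (reference angle, axis) cell
    and per reference angle pooled over axes.

    A cell with a single measurement keeps its mean but has its SD omitted
    with a warning; cells need at least one measurement to be reported.
    """
    trials = list(trials)
    if not trials:
        raise ValidationError("no trials to summarize")
    values: dict[tuple[float, str], list[float]] = {}
    for tr in trials:
        values.setdefault((float(tr.reference_angle), tr.axis), []).append(tr.measured_angle)
        values.setdefault((float(tr.reference_angle), "All"), []).append(tr.measured_angle)
    cells: dict[tuple[float, str], SummaryCell] = {}
    for key, vals in values.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            warnings.warn(
                f"cell {key} has n={len(v)} < 2; SD omitted", stacklevel=2
            )
            cells[key] = SummaryCell(mean=float(v.mean()), sd=None, n=len(v))
        else:
            cells[key] = SummaryCell(
                mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v)
            )
    return SummaryTable(cells=cells)


def load_reference_fixture() -> list[ReferenceTrial]:
    """The 108 printed bench measurements (3 angles x 3 axes x 4 operators
    x 3 repetitions)."""
    with resources.files("wristkin.data").joinpath("reference_trials.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return [
        ReferenceTrial(
            operator=int(r.operator),
            axis=str(r.axis),
            reference_angle=float(r.reference_angle),
            repetition=int(r.repetition),
            measured_angle=float(r.measured_angle),
        )
        for r in df.itertuples()
    ]


def mixed_model_fit(trials: Sequence[ReferenceTrial]):
    """Convenience delegation to a general-purpose mixed-model fit.

    Fits measured angle ~ C(reference_angle) * C(axis) with a random
    operator intercept via statsmodels MixedLM.  This is a labelled
    convenience only: it is not the original nlme/AR(1) analysis and no
    numerical equivalence is claimed.  Returns the fitted results object.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame([t.__dict__ for t in trials])
    model = smf.mixedlm(
        "measured_angle ~ C(reference_angle) * C(axis)", df, groups=df["operator"]
    )
    return model.fit()
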