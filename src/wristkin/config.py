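"""Run configuration: TOML file with full defaults, unknown keys rejected.

Sections mirror the pipeline stages::

    [fusion]   method, alpha, q_angle, q_bias, r_angle, gravity_mag
    [arm]      len_ab_m, len_ac_m, plus [arm.operators.<id>] overrides
    [risk]     low_max_deg, med_max_deg, cut_threshold, cut_min_gap,
               cut_onset_floor
    [synth]    accel_sigma, gyro_sigma, gyro_bias, seed, scenario knobs

A missing file or empty table means "all defaults"; a key that is not
recognised is a configuration error (exit code 2 at the CLI).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

from .fusion import FilterConfig
from .imu_core import ValidationError, WristkinError
from .kinematics import ArmModel
from .risk import RiskThresholds
from .synth import NoiseModel, PruningScenario

__all__ = ["ConfigError", "CutDetectConfig", "RunConfig", "load_config"]


class ConfigError(WristkinError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class CutDetectConfig:
    threshold: float = 2.0
    min_gap: float = 0.5
    onset_floor: float = 0.15


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with documented defaults."""

    fusion: FilterConfig = field(default_factory=FilterConfig)
    arm: ArmModel = field(default_factory=ArmModel)
    arm_by_operator: dict[int, ArmModel] = field(default_factory=dict)
    risk: RiskThresholds = field(default_factory=RiskThresholds)
    cut_detect: CutDetectConfig = field(default_factory=CutDetectConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    scenario: PruningScenario = field(default_factory=PruningScenario)
    seed: int = NoiseModel().seed
    verbosity: int = 0

    def arm_for(self, operator: int | None) -> ArmModel:
        if operator is not None and operator in self.arm_by_operator:
            return self.arm_by_operator[operator]
        return self.arm


def _build(cls, table: dict, rename: dict[str, str] | None = None, what: str = ""):
    rename = rename or {}
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in table.items():
        name = rename.get(key, key)
        if name not in known:
            raise ConfigError(f"unknown key {key!r} in [{what}]")
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (ValidationError, TypeError) as exc:
        raise ConfigError(f"invalid [{what}] section: {exc}") from exc


def load_config(path=None) -> RunConfig:
    """Load a TOML config; ``None`` returns the full-default configuration."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML: {exc}") from exc

    known_sections = {"fusion", "arm", "risk", "synth", "seed", "verbosity"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    cfg = RunConfig()
    if "fusion" in raw:
        cfg.fusion = _build(FilterConfig, raw["fusion"], what="fusion")

    if "arm" in raw:
        arm_tbl = dict(raw["arm"])
        per_op = arm_tbl.pop("operators", {})
        cfg.arm = _build(
            ArmModel, arm_tbl, rename={"len_ab_m": "len_ab", "len_ac_m": "len_ac"}, what="arm"
        )
        for op, tbl in per_op.items():
            cfg.arm_by_operator[int(op)] = _build(
                ArmModel, tbl, rename={"len_ab_m": "len_ab", "len_ac_m": "len_ac"},
                what=f"arm.operators.{op}",
            )

    if "risk" in raw:
        risk_tbl = dict(raw["risk"])
        cut_tbl = {
            name: risk_tbl.pop(key)
            for key, name in (
                ("cut_threshold", "threshold"),
                ("cut_min_gap", "min_gap"),
                ("cut_onset_floor", "onset_floor"),
            )
            if key in risk_tbl
        }
        cfg.risk = _build(
            RiskThresholds, risk_tbl,
            rename={"low_max_deg": "low_max", "med_max_deg": "med_max"}, what="risk",
        )
        cfg.cut_detect = _build(CutDetectConfig, cut_tbl, what="risk")

    if "synth" in raw:
        synth_tbl = dict(raw["synth"])
        noise_tbl = {
            k: synth_tbl.pop(k)
            for k in ("accel_sigma", "gyro_sigma", "gyro_bias", "seed")
            if k in synth_tbl
        }
        if "gyro_bias" in noise_tbl:
            noise_tbl["gyro_bias"] = tuple(noise_tbl["gyro_bias"])
        cfg.noise = _build(NoiseModel, noise_tbl, what="synth")
        cfg.scenario = _build(PruningScenario, synth_tbl, what="synth")

    if "seed" in raw:
        cfg.seed = int(raw["seed"])
        cfg.noise = NoiseModel(
            accel_sigma=cfg.noise.accel_sigma,
            gyro_sigma=cfg.noise.gyro_sigma,
            gyro_bias=cfg.noise.gyro_bias,
            seed=cfg.seed,
        )
    if "verbosity" in raw:
        cfg.verbosity = int(raw["verbosity"])
    return cfg
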