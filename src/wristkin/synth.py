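"""Synthetic session generator: ground-truth wrist trajectories and the
three consistent noisy IMU streams they imply.

The generator inverts the estimation model so every downstream module can
be tested without hardware: a C^1 wrist-angle trajectory (smoothstep
between keyframes, so the angular velocity is analytically known) is
converted per sensor into body-frame gyro rates through the exact
Euler-rate mapping, and into accelerometer readings as gravity rotated
into the sensor frame, plus programmed burst accelerations on the hand
sensor and Gaussian noise/bias from a seeded generator.

Two laboratory protocols are emulated:

* reference-angle trials -- neutral -> target -> hold -> return, three
  repetitions, targets 15/45/60 degrees about a single axis;
* simulated-vine pruning -- 7 cuts per sequence, 3 sequences, each cut a
  ramp to per-cut peak wrist angles with a raised-cosine acceleration
  burst (the cutting action) centred on the hold.

Everything is deterministic under a fixed seed: the same NoiseModel seed
yields bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fusion import GRAVITY, euler_rate_matrix, euler_to_matrix, matrix_to_euler
from .imu_core import ImuStream, SessionRecording, ValidationError
from .kinematics import ArmModel
from .risk import CutEvent

__all__ = [
    "TrajectorySpec",
    "NoiseModel",
    "PruningScenario",
    "Truth",
    "TrialTruth",
    "generate_trajectory",
    "synthesize_imu",
    "generate_reference_trial",
    "generate_pruning_session",
]

DEFAULT_SEED = 20240902


def _smoothstep(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """s(u) = 3u^2 - 2u^3 and its derivative on [0, 1]."""
    return u * u * (3.0 - 2.0 * u), 6.0 * u * (1.0 - u)


@dataclass
class TrajectorySpec:
    """Keyframed wrist-angle trajectory: (time s, euler degrees) pairs with
    smoothstep interpolation, held flat outside the keyframe span."""

    keyframes: list[tuple[float, Sequence[float]]]
    rate: float = 50.0

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ValidationError("need at least one keyframe")
        times = [t for t, _ in self.keyframes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("keyframe times must be strictly increasing")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Angles (deg) and Euler-angle rates (deg/s) at times t."""
        times = np.array([k[0] for k in self.keyframes])
        values = np.array([np.asarray(k[1], dtype=float) for k in self.keyframes])
        angles = np.empty((t.shape[0], 3))
        rates = np.zeros((t.shape[0], 3))
        angles[t <= times[0]] = values[0]
        angles[t >= times[-1]] = values[-1]
        for i in range(len(times) - 1):
            t0, t1 = times[i], times[i + 1]
            # closed interval: adjacent segments agree at shared keyframes
            mask = (t >= t0) & (t <= t1)
            if not mask.any():
                continue
            u = (t[mask] - t0) / (t1 - t0)
            s, ds = _smoothstep(u)
            dv = values[i + 1] - values[i]
            angles[mask] = values[i] + np.outer(s, dv)
            rates[mask] = np.outer(ds / (t1 - t0), dv)
        return angles, rates


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor imperfections: white noise sigmas (accel m/s^2,
    gyro deg/s), a constant per-axis gyro bias (deg/s), and the RNG seed."""

    accel_sigma: float = 0.05
    gyro_sigma: float = 0.5
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.accel_sigma < 0 or self.gyro_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")

    @classmethod
    def none(cls, seed: int = DEFAULT_SEED) -> "NoiseModel":
        return cls(accel_sigma=0.0, gyro_sigma=0.0, seed=seed)


@dataclass
class Truth:
    """Ground-truth kinematic state on the sample grid."""

    t: np.ndarray
    wrist_euler: np.ndarray  # (n, 3) degrees, hand relative to forearm
    wrist_rates: np.ndarray  # (n, 3) deg/s Euler-angle rates
    forearm_euler: np.ndarray
    forearm_rates: np.ndarray
    pulse: np.ndarray  # (n,) hand-sensor burst acceleration, m/s^2
    rate: float


@dataclass
class TrialTruth(Truth):
    """Truth plus protocol annotations for oracle tests."""

    hold_windows: list[tuple[float, float]] = field(default_factory=list)
    cut_events: list[CutEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def generate_trajectory(
    spec: TrajectorySpec,
    duration: float | None = None,
    forearm_spec: TrajectorySpec | None = None,
) -> Truth:
    """Evaluate a keyframed wrist trajectory on the uniform sample grid.

    The forearm is held at the zero reference unless ``forearm_spec`` is
    given.  Rates are the analytic smoothstep derivatives, so the
    programmed angular velocity is exactly the time derivative of the
    programmed angles.
    """
    end = duration if duration is not None else spec.keyframes[-1][0]
    n = int(round(end * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    wrist, wrist_rates = spec.sample(t)
    if forearm_spec is None:
        forearm = np.zeros((n, 3))
        forearm_rates = np.zeros((n, 3))
    else:
        forearm, forearm_rates = forearm_spec.sample(t)
    return Truth(
        t=t,
        wrist_euler=wrist,
        wrist_rates=wrist_rates,
        forearm_euler=forearm,
        forearm_rates=forearm_rates,
        pulse=np.zeros(n),
        rate=spec.rate,
    )


def _body_rates(euler: np.ndarray, euler_rates: np.ndarray) -> np.ndarray:
    """omega_body = M(theta) @ theta_dot, row-wise (deg/s)."""
    out = np.empty_like(euler_rates)
    for k in range(euler.shape[0]):
        out[k] = euler_rate_matrix(euler[k]) @ euler_rates[k]
    return out


def synthesize_imu(
    truth: Truth,
    placement: ArmModel | None = None,
    noise: NoiseModel | None = None,
    gravity_mag: float = GRAVITY,
) -> SessionRecording:
    """Render a Truth into a three-sensor SessionRecording.

    S2 rides the hand segment (forearm pose composed with the wrist
    rotation), S1 and S3 the forearm.  Per sensor: gyro = body angular
    rate + bias + white noise; accel = gravity rotated into the sensor
    frame + the programmed burst (hand sensor, collinear with the sensed
    gravity direction so the magnitude excess equals the pulse) + white
    noise.  Deterministic for a fixed noise seed.

    Lever-arm (centripetal/tangential) accelerations of the mounting
    points are not modelled; ``placement`` is carried through for
    downstream kinematics.
    """
    noise = noise if noise is not None else NoiseModel()
    placement = placement or ArmModel()
    rng = np.random.default_rng(noise.seed)
    n = truth.t.shape[0]

    Rw = euler_to_matrix(truth.wrist_euler)
    Rf = euler_to_matrix(truth.forearm_euler)
    omega_w = _body_rates(truth.wrist_euler, truth.wrist_rates)
    omega_f = _body_rates(truth.forearm_euler, truth.forearm_rates)

    hand_euler = np.empty((n, 3))
    hand_omega = np.empty((n, 3))
    Rh = np.einsum("nij,njk->nik", Rf, Rw)
    for k in range(n):
        hand_euler[k], _ = matrix_to_euler(Rh[k])
        # omega(R_f R_w) = R_w^T omega_f + omega_w (exact composition rule)
        hand_omega[k] = Rw[k].T @ omega_f[k] + omega_w[k]

    g_world = np.array([0.0, 0.0, gravity_mag])
    streams: dict[str, ImuStream] = {}
    for sid, R, omega in (
        ("S1", Rf, omega_f),
        ("S2", Rh, hand_omega),
        ("S3", Rf, omega_f),
    ):
        accel = np.einsum("nji,j->ni", R, g_world)  # R^T g per frame
        if sid == "S2" and np.any(truth.pulse):
            accel = accel * (1.0 + truth.pulse / gravity_mag)[:, None]
        accel = accel + rng.normal(0.0, noise.accel_sigma, size=(n, 3))
        gyro = omega + np.asarray(noise.gyro_bias, dtype=float)
        gyro = gyro + rng.normal(0.0, noise.gyro_sigma, size=(n, 3))
        streams[sid] = ImuStream(sid, truth.t.copy(), accel, gyro, truth.rate)
    return SessionRecording(streams=streams, placement=placement)


def _axis_euler(angle: float, axis: str) -> np.ndarray:
    out = np.zeros(3)
    out[{"X": 0, "Y": 1, "Z": 2}[str(axis).upper()]] = angle
    return out


def generate_reference_trial(
    angle: float,
    axis: str,
    noise: NoiseModel | None = None,
    n_repetitions: int = 3,
    rate: float = 50.0,
    placement: ArmModel | None = None,
) -> tuple[SessionRecording, TrialTruth]:
    """One bench reliability trial: neutral -> target -> hold -> return,
    repeated ``n_repetitions`` times (protocol default 3).

    ``angle`` must be one of the protocol references {15, 45, 60} degrees
    and ``axis`` one of X/Y/Z.  Returns the session and a TrialTruth whose
    ``hold_windows`` mark the settled portion of each hold for oracle
    comparisons.
    """
    if float(angle) not in (15.0, 45.0, 60.0):
        raise ValidationError(f"reference angle must be 15, 45 or 60, got {angle}")
    target = _axis_euler(float(angle), axis)
    lead, ramp, hold = 1.0, 1.0, 2.0
    keyframes: list[tuple[float, Sequence[float]]] = [(0.0, np.zeros(3))]
    hold_windows = []
    t0 = lead
    for _ in range(n_repetitions):
        keyframes += [
            (t0, np.zeros(3)),
            (t0 + ramp, target),
            (t0 + ramp + hold, target),
            (t0 + 2 * ramp + hold, np.zeros(3)),
        ]
        # trim the hold edges so filter settling is excluded from oracles
        hold_windows.append((t0 + ramp + 0.25, t0 + ramp + hold - 0.25))
        t0 += 2 * ramp + hold + 1.0
    spec = TrajectorySpec(keyframes=keyframes, rate=rate)
    truth = generate_trajectory(spec, duration=t0)
    trial = TrialTruth(
        **truth.__dict__,
        hold_windows=hold_windows,
        meta={"reference_angle": float(angle), "axis": str(axis).upper(),
              "repetitions": n_repetitions},
    )
    session = synthesize_imu(trial, placement=placement, noise=noise)
    session.metadata.update(trial.meta, scenario="reference_trial")
    return session, trial


@dataclass
class PruningScenario:
    """The simulated-vine cutting protocol.

    Paper-faithful preset: 7 cuts per sequence, 3 sequences per operator.
    ``peak_angles`` holds the per-cut peak wrist angles as an
    (n_sequences, n_cuts, 3) array in degrees; None samples the printed
    field-trial angles for the chosen operator.  Bursts are raised-cosine
    acceleration pulses on the hand sensor, centred on each cut's hold.
    """

    n_cuts: int = 7
    n_sequences: int = 3
    peak_angles: np.ndarray | None = None
    inter_cut_rest: float = 1.0
    inter_seq_rest: float = 2.0
    ramp: float = 0.5
    hold: float = 0.4
    burst_amplitude: float = 8.0
    burst_duration: float = 0.3
    rate: float = 50.0

    def __post_init__(self) -> None:
        if self.n_cuts < 1 or self.n_sequences < 1:
            raise ValidationError("need at least one cut and one sequence")
        if self.burst_duration >= self.hold + 2 * self.ramp:
            raise ValidationError("burst_duration must fit inside the cut cycle")
        if self.peak_angles is not None:
            pa = np.asarray(self.peak_angles, dtype=float)
            if pa.shape != (self.n_sequences, self.n_cuts, 3):
                raise ValidationError(
                    f"peak_angles shape {pa.shape} != ({self.n_sequences}, {self.n_cuts}, 3)"
                )
            self.peak_angles = pa


def _fixture_peaks(operator: int, scenario: PruningScenario) -> np.ndarray:
    """Per-cut peak angles sampled from the printed field-trial table."""
    from .risk import load_pruning_fixture

    df = load_pruning_fixture()
    sub = df[df.operator == operator]
    if sub.empty:
        raise ValidationError(f"no fixture angles for operator {operator}")
    peaks = np.zeros((scenario.n_sequences, scenario.n_cuts, 3))
    axis_col = {"X": 0, "Y": 1, "Z": 2}
    for r in sub.itertuples():
        if r.sequence <= scenario.n_sequences and r.cut <= scenario.n_cuts:
            peaks[r.sequence - 1, r.cut - 1, axis_col[r.axis]] = r.angle_deg
    return peaks


def generate_pruning_session(
    scenario: PruningScenario | None = None,
    operator: int = 1,
    noise: NoiseModel | None = None,
    placement: ArmModel | None = None,
) -> tuple[SessionRecording, TrialTruth]:
    """A full pruning session for one operator.

    Each cut: ramp from neutral to the cut's peak wrist angles, hold while
    the acceleration burst (the cutting action) fires, ramp back, rest.
    Sequences are separated by a longer rest.  Returns the session plus a
    TrialTruth carrying the ground-truth CutEvents (burst support window
    and programmed peak angles) for oracle testing.
    """
    scenario = scenario or PruningScenario()
    peaks = (
        np.asarray(scenario.peak_angles, dtype=float)
        if scenario.peak_angles is not None
        else _fixture_peaks(operator, scenario)
    )

    lead = 1.0
    keyframes: list[tuple[float, Sequence[float]]] = [(0.0, np.zeros(3))]
    cut_events: list[CutEvent] = []
    t0 = lead
    for s in range(scenario.n_sequences):
        for c in range(scenario.n_cuts):
            peak = peaks[s, c]
            keyframes += [
                (t0, np.zeros(3)),
                (t0 + scenario.ramp, peak),
                (t0 + scenario.ramp + scenario.hold, peak),
                (t0 + 2 * scenario.ramp + scenario.hold, np.zeros(3)),
            ]
            b0 = t0 + scenario.ramp + 0.5 * (scenario.hold - scenario.burst_duration)
            cut_events.append(
                CutEvent(start=b0, end=b0 + scenario.burst_duration, peak_angles=peak)
            )
            t0 += 2 * scenario.ramp + scenario.hold + scenario.inter_cut_rest
        t0 += scenario.inter_seq_rest
    spec = TrajectorySpec(keyframes=keyframes, rate=scenario.rate)
    truth = generate_trajectory(spec, duration=t0)

    pulse = np.zeros_like(truth.t)
    for ev in cut_events:
        mask = (truth.t >= ev.start) & (truth.t <= ev.end)
        u = (truth.t[mask] - ev.start) / scenario.burst_duration
        pulse[mask] = 0.5 * scenario.burst_amplitude * (1.0 - np.cos(2.0 * np.pi * u))
    truth.pulse = pulse

    trial = TrialTruth(
        **truth.__dict__,
        cut_events=cut_events,
        meta={"operator": operator, "n_cuts": scenario.n_cuts,
              "n_sequences": scenario.n_sequences},
    )
    session = synthesize_imu(trial, placement=placement, noise=noise)
    session.metadata.update(trial.meta, scenario="pruning")
    return session, trial
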