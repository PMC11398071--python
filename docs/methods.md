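# Methods

This note records the modelling choices, parameter defaults and numerical
conventions behind `wristkin`, and what the synthetic-data tests do and do
not demonstrate about real recordings.

## Sensor and signal model

Each of the three body-mounted sensors reports a timestamped specific
force (accelerometer, m/s², gravity included) and angular rate (gyroscope,
deg/s) in its own frame at a nominal 50 Hz. Timestamps are assigned by the
receiver, which polls sensors round-robin; the package treats them as
authoritative and never re-derives time from sample index. Synchronization
places the three streams on an exact arithmetic grid of step 1/rate over
their common interval, matching each grid point to the nearest sample per
sensor; a frame is dropped (and counted) if any match is further than
`max_skew`, default half a polling cycle (10 ms at 50 Hz) — the bound a
round-robin read imposes by construction.

The on-disk session format is a plain CSV
(`sensor_id,t,ax,ay,az,gx,gy,gz`, UTF-8, `.` decimal separator) with
shortest round-trip float formatting, so write∘read is the identity. Units
are fixed at the I/O boundary (m/s², deg/s, degrees); all trigonometry is
done in radians internally.

## Orientation

Euler convention: the rotation is composed as R = Rx(θx)·Ry(θy)·Rz(θz),
matching the order of the kinematic-chain product used throughout
(T·Rx·Ry·Rz). θy is confined to (−90°, 90°); decompositions within 0.5° of
the pole are returned on the θz = 0 branch and gimbal-flagged rather than
rejected, since wrist motion rarely approaches the pole but filters must
not crash when noise pushes an estimate near it.

Gyro integration solves the Euler-rate mapping ω_body = M(θ)·θ̇, with
M = [[cosθy·cosθz, sinθz, 0], [−cosθy·sinθz, cosθz, 0], [sinθy, 0, 1]],
using Heun's method (explicit trapezoid), which is second order: halving
the step reduces the error on smooth trajectories by ≈4×, and constant-
rate input is integrated exactly. At the (unreachable-in-practice) pole
where M is singular the naive identity mapping is used for that step.

Accelerometer tilt inverts the static reading a = Rᵀ(0,0,g) for roll and
pitch. Because this Euler order applies yaw innermost, the gravity
direction in the sensor frame depends on θz; the fusion loop therefore
de-rotates the measured vector by the current yaw estimate before
extracting tilt (the standalone `accel_tilt` assumes yaw 0). Tilt is only
trusted when ‖a‖ is within ±30% of g; outside that band the sample is
treated as dynamic and the filter coasts on the gyro. Yaw itself has no
reference without a magnetometer: it is gyro-integrated and implicitly
zeroed at session start, so reported θz is relative to the starting
heading.

The complementary filter blends per axis with gyro weight α = 0.98 at
50 Hz (time constant ≈1 s): fast motion follows the gyro, static error
decays geometrically to the tilt reference, and a constant gyro bias b
produces a bounded steady-state roll/pitch error ≈ α/(1−α)·b·Δt (≈1° per
deg/s at the defaults) instead of the b·t drift of open-loop integration.
α = 1 degenerates exactly to gyro-only integration, including the initial
attitude. The Kalman alternative runs three decoupled 2-state (angle,
bias) filters with the gyro step as process model and tilt as measurement
(defaults q_angle = 0.01 deg²/s, q_bias = 0.003 deg²/s, r_angle =
0.5 deg²); the decoupling ignores inter-axis geometry and is intended for
near-static and single-axis regimes, which is why the complementary filter
is the default.

## Motion

Gravity-free acceleration is the vector subtraction
a_real = a_measured − R(θ)ᵀ·(0,0,g) with g = 9.81 m/s² by default.
Velocity and position follow by trapezoid integration. Double integration
of noise grows as t³ in variance, so a zero-velocity update is available:
rest is declared when the gyro magnitude stays below 2 deg/s and
| ‖a‖ − g | below 0.3 m/s² for at least 0.2 s, and velocity is clamped to
zero there. Risk analysis uses angles only; positions are computed but
carry no classification weight.

## Arm model and wrist angles

The hand–wrist–forearm system is a two-segment rigid chain hinged at the
wrist axis A: hand segment AB (default 0.18 m) and forearm segment AC
(default 0.26 m), both resting along +Y/−Y, with S2 and S3 at the segment
midpoints. Segment lengths are per-operator configuration — anthropometric
adaptability is a design goal — and forward kinematics of the hand point N
preserves ‖N − A‖ = len_AB for every angle input. The wrist angle series
is the Euler decomposition of R_forearmᵀ·R_hand per synchronized frame;
S1 serves event-reference/cut-detection duties only. The resting-pose
frame assignment (segments along Y, world z up) is a package convention;
equivalent choices rotate all reported angles consistently.

## Risk classification

Bands on |angle|: low [0, 20], medium (20, 45], high (45, ∞) degrees, with
45.00° counted medium — the only boundary convention consistent with
reproducing the published frequency table from the printed per-cut angles
(a printed 45.11° is high, printed 45.00° entries are medium). Percentages
are truncated (floor), not rounded: 9/84 → 10%, 48/84 → 57%. Under these
rules the package reproduces the published high-band row exactly (X 10%,
Y 57%, Z 52%, pooled 40%) and the X/Z/pooled low cells; the remaining
printed cells (X-med 33%, Y-med 35%, Y-low 8%, Z-med 18%, pooled-med 28%)
are not reproducible from the printed angles under any single rounding
rule (the counts give 32, 33, 9, 16 and 27 respectively) and are
documented here rather than forced. Whether the printed per-cut angles are
peaks, means or endpoints is unstated in the source material; this package
defines the representative angle of a cut window as the signed angle of
maximal absolute value per axis, matching how RULA-style methods score the
worst posture.

The bench summary (mean ± sample SD, n−1 denominator, round-half-even to
2 decimals at the output boundary only) reproduces 11 of the 12 published
cells; the pooled 60°/All mean is 60.08 by raw-value pooling of all 36
measurements, while the published table prints 60.07 — obtainable only by
averaging the already-rounded per-axis means. The package pools raw
values, as it does for the 45°/All cell (45.17 ± 0.80, which matches).
The published mixed-effects significance analysis is out of scope; a
clearly-labelled convenience (`reliability.mixed_model_fit`) delegates an
approximate fit to statsmodels MixedLM with a random operator intercept
and no autoregressive structure, with no numerical claims attached.

## Cut detection

The excess signal e(t) = | ‖a(t)‖ − g | on the hand sensor is thresholded
at 2 m/s² (default), super-threshold regions closer than 0.5 s are merged,
and each region is extended outward while e exceeds a 0.15 m/s² onset
floor (≈3× the default noise sigma on the magnitude). Because a smooth
burst leaves zero quadratically, √e is locally linear on the flank; the
edge is refined by extrapolating √e to zero, clipped to two samples, which
places detected onsets within one sample of the true burst start at the
default noise. With an expected count, the strongest k bursts are returned
in time order and a shortfall warns rather than fails. Detection is
invariant to time translation of the stream.

## Synthetic data generator

The generator defines the study conditions and inverts the estimation
model exactly: wrist-angle trajectories are keyframed with smoothstep
(3u² − 2u³) interpolation so the angular velocity is continuous and
analytic; per sensor, gyro = M(θ)·θ̇ (+ bias + white noise) and
accel = Rᵀ(0,0,g) (+ burst + white noise). Default noise — accel σ =
0.05 m/s², gyro σ = 0.5 deg/s, zero bias — is typical of consumer MEMS
parts at 50 Hz. Sessions are bit-identical under a fixed seed (default
20240902).

The reference-trial scenario mirrors the bench protocol: neutral → 1 s
ramp → 2 s hold → return, three repetitions, targets 15/45/60° about one
axis; recorded hold windows are trimmed by 0.25 s per side so oracles
compare settled estimates. The pruning scenario mirrors the field
protocol: 7 cuts per sequence, 3 sequences, each cut a 0.5 s ramp to the
per-cut peak angles, a 0.4 s hold carrying a 0.3 s raised-cosine
acceleration burst of 8 m/s² (applied collinear with the sensed gravity
direction so the magnitude excess equals the pulse), 1 s between cuts and
2 s between sequences. Peak angles default to the printed field-trial
table for the chosen operator, so the classifier path can be exercised
end to end against known inputs.

What synthetic passes do not show: the generator omits lever-arm
(centripetal/tangential) accelerations at the mounting points, soft-tissue
artefact, sensor misalignment on the skin, temperature-dependent bias
walk, and any operator-to-operator variability beyond the noise scale.
Round-trip accuracy on synthetic sessions therefore bounds algorithmic
error, not field error; the bench fixture is the only real-data anchor.

## Problem sizes and numerics

The test suite and acceptance script use the protocol-sized problems
throughout: 108 bench trials, 252 field angles, 1000 random poses for the
transform oracle (agreement to 1e−12 against literal matrix products,
orthonormality and det = +1 asserted to 1e−9 on every construction),
100 seeded noisy reference trials for the recovery rate, and two full
21-cut pruning sessions for detection. Tie-breaks: nearest-sample
synchronization prefers the earlier sample on exact ties; risk bands are
closed on their upper edge; two-decimal reporting uses banker's rounding
on the shortest decimal representation.

## Known limitations

Yaw is relative to session start and drifts with gyro noise (random walk,
≈0.5° over a minute at default noise). The decoupled Kalman variant is
approximate for large multi-axis excursions. The Euler parameterisation
degrades near θy = ±90°, which normal wrist range does not reach but a
dropped or re-strapped sensor could. Dead-reckoned position is unusable
beyond a few seconds without zero-velocity updates and is provided for
completeness, not for risk scoring.
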