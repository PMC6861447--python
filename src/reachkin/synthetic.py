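"""Synthetic paired-trial generator.

Emulates the validation study's recording setup: a participant's wrist
carries both an IMU (100 Hz accel/gyro) and an optical marker tracked at
200 Hz while they perform a scripted reach-manipulate-return task (block,
drink, or pour). Each task is a sequence of straight-line minimum-jerk
segments separated by stationary dwells, so every trial has closed-form
position/velocity/acceleration and therefore exact ground-truth metrics.

Modest scripted wrist rotations (minimum-jerk angle profiles about the
sensor x-axis, net zero across the trial) accompany each segment: reaching
naturally rotates the forearm, and the downstream sectioning rules key on
angular speed, so a rotation-free trial would be unrealistic and
unsegmentable. The hand starts pronated with the sensor z-axis opposing
gravity.

All randomness is seeded; constructing a TrialSpec without a seed raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import (
    ACCEL_RANGE_G,
    EXPECTED_PEAKS,
    GRAVITY,
    GYRO_RANGE_DPS,
    GroundTruth,
    ImuTrial,
    MarkerTrial,
)

_IMU_STREAM = 0
_MARKER_STREAM = 1

#: Closed-form peak-speed factor of the minimum-jerk profile.
MINJERK_PEAK_FACTOR = 1.875


# ---------------------------------------------------------------------------
# minimum-jerk primitives
# ---------------------------------------------------------------------------

def minimum_jerk_position(amplitude: float, duration: float, t) -> np.ndarray:
    """Position along a minimum-jerk point-to-point reach.

    p(t) = amplitude * (10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/duration.
    Velocity and acceleration vanish at both endpoints; peak speed is
    1.875 * amplitude / duration at t = duration/2.

    Raises ValueError if any t lies outside [0, duration].
    """
    t = np.asarray(t, dtype=np.float64)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if np.any(t < 0) or np.any(t > duration):
        raise ValueError("t outside [0, duration]")
    tau = t / duration
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def minimum_jerk_velocity(amplitude: float, duration: float, t) -> np.ndarray:
    """First derivative of :func:`minimum_jerk_position`."""
    t = np.asarray(t, dtype=np.float64)
    tau = t / duration
    return amplitude / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)


def minimum_jerk_acceleration(amplitude: float, duration: float, t) -> np.ndarray:
    """Second derivative of :func:`minimum_jerk_position`."""
    t = np.asarray(t, dtype=np.float64)
    tau = t / duration
    return amplitude / duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)


# ---------------------------------------------------------------------------
# trial specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """One straight-line reach segment followed by a stationary dwell."""

    amplitude: tuple  # displacement (m) per earth axis, length 3
    duration: float  # s
    dwell_after: float = 0.0  # s of stationary hold after the segment
    rotation_deg: float = 0.0  # scripted wrist rotation about sensor x

    def __post_init__(self):
        object.__setattr__(self, "amplitude",
                           tuple(float(a) for a in self.amplitude))
        if len(self.amplitude) != 3:
            raise ValueError("amplitude must have 3 components")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.dwell_after < 0:
            raise ValueError("dwell_after must be non-negative")

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.amplitude))

    @property
    def peak_speed(self) -> float:
        return MINJERK_PEAK_FACTOR * self.distance / self.duration


@dataclass(frozen=True)
class TrialSpec:
    """Full description of one simulated paired trial."""

    task: str
    segments: tuple  # of SegmentSpec
    seed: int
    lead_in: float = 2.0
    lead_out: float = 2.0
    imu_rate: float = 100.0
    marker_rate: float = 200.0
    accel_noise_sd: float = 0.02  # g
    gyro_noise_sd: float = 0.5  # deg/s
    accel_bias: tuple = (0.0, 0.0, 0.0)  # g per axis
    marker_noise_sd: float = 0.5  # mm
    trial_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "accel_bias",
                           tuple(float(b) for b in self.accel_bias))
        if self.task not in EXPECTED_PEAKS:
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.segments) != EXPECTED_PEAKS[self.task]:
            raise ValueError(
                f"task {self.task!r} requires {EXPECTED_PEAKS[self.task]} "
                f"segments (one per expected velocity peak), got "
                f"{len(self.segments)}"
            )
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("TrialSpec requires an integer seed; unseeded "
                             "generation is not supported")
        if self.imu_rate <= 0 or self.marker_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if min(self.accel_noise_sd, self.gyro_noise_sd,
               self.marker_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.lead_in < 0 or self.lead_out < 0:
            raise ValueError("lead_in/lead_out must be non-negative")


# ---------------------------------------------------------------------------
# trajectory composition
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Analytic piecewise trajectory of the wrist for one trial."""

    spec: TrialSpec
    seg_onsets: np.ndarray  # s, absolute
    seg_offsets: np.ndarray
    total_duration: float
    ground_truth: GroundTruth = field(default=None)

    def _accumulate(self, t, shape_fn, scale_fn):
        """Sum per-segment contributions: 0 before, shape during, 1 after."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        out = np.zeros((len(t), 3))
        for seg, on, off in zip(self.spec.segments, self.seg_onsets,
                                self.seg_offsets):
            amp = np.asarray(seg.amplitude)
            during = (t >= on) & (t <= off)
            if np.any(during):
                tt = np.clip(t[during] - on, 0.0, seg.duration)
                out[during] += np.outer(shape_fn(seg, tt), amp)
            after = t > off
            out[after] += scale_fn(seg) * amp
        return out

    def position(self, t) -> np.ndarray:
        """Earth-frame position (m) relative to the start, shape (n, 3)."""
        return self._accumulate(
            t,
            lambda seg, tt: minimum_jerk_position(1.0, seg.duration, tt),
            lambda seg: 1.0,
        )

    def velocity(self, t) -> np.ndarray:
        return self._accumulate(
            t,
            lambda seg, tt: minimum_jerk_velocity(1.0, seg.duration, tt),
            lambda seg: 0.0,
        )

    def acceleration(self, t) -> np.ndarray:
        return self._accumulate(
            t,
            lambda seg, tt: minimum_jerk_acceleration(1.0, seg.duration, tt),
            lambda seg: 0.0,
        )

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(self.velocity(t), axis=1)

    def _rot(self, t, fn) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        out = np.zeros(len(t))
        for seg, on, off in zip(self.spec.segments, self.seg_onsets,
                                self.seg_offsets):
            during = (t >= on) & (t <= off)
            if np.any(during):
                tt = np.clip(t[during] - on, 0.0, seg.duration)
                out[during] += fn(seg.rotation_deg, seg.duration, tt)
            if fn is minimum_jerk_position:
                out[t > off] += seg.rotation_deg
        return out

    def wrist_angle_deg(self, t) -> np.ndarray:
        """Scripted wrist rotation angle (deg) about the sensor x-axis."""
        return self._rot(t, minimum_jerk_position)

    def wrist_rate_dps(self, t) -> np.ndarray:
        """Angular speed (deg/s) of the scripted rotation."""
        return self._rot(t, minimum_jerk_velocity)

    def sample(self, rate: float) -> dict:
        """Dense arrays of the trajectory at `rate` Hz over the full trial."""
        n = int(np.floor(self.total_duration * rate)) + 1
        t = np.arange(n) / rate
        return {
            "t": t,
            "pos": self.position(t),
            "vel": self.velocity(t),
            "acc": self.acceleration(t),
            "speed": self.speed(t),
        }


def compose_trajectory(spec: TrialSpec) -> Trajectory:
    """Concatenate minimum-jerk segments and exact dwells into a trajectory.

    The trajectory begins and ends stationary at the start position when the
    segment displacements sum to zero (the default task scripts do); the
    resultant speed has exactly one local maximum per segment.
    """
    onsets, offsets = [], []
    t_cursor = spec.lead_in
    for seg in spec.segments:
        onsets.append(t_cursor)
        t_cursor += seg.duration
        offsets.append(t_cursor)
        t_cursor += seg.dwell_after
    total = t_cursor + spec.lead_out
    traj = Trajectory(
        spec=spec,
        seg_onsets=np.array(onsets),
        seg_offsets=np.array(offsets),
        total_duration=total,
    )
    traj.ground_truth = _ground_truth(traj)
    return traj


def _ground_truth(traj: Trajectory) -> GroundTruth:
    from .metrics import SparcParams, sparc  # local to avoid import cycles

    spec = traj.spec
    onset = float(traj.seg_onsets[0])
    offset = float(traj.seg_offsets[-1])
    mt_ms = (offset - onset) * 1000.0
    pv = max(seg.peak_speed for seg in spec.segments)
    # smoothness truth: SPARC of the noiseless speed over the movement,
    # sampled at the IMU rate
    n = int(round((offset - onset) * spec.imu_rate)) + 1
    t = onset + np.arange(n) / spec.imu_rate
    sp = traj.speed(np.clip(t, 0, traj.total_duration))
    true_sparc = sparc(sp, spec.imu_rate, SparcParams())
    return GroundTruth(
        movement_time_ms=mt_ms,
        peak_velocity_ms=pv,
        sparc=true_sparc,
        onset_s=onset,
        offset_s=offset,
        segment_onsets_s=[float(x) for x in traj.seg_onsets],
        segment_offsets_s=[float(x) for x in traj.seg_offsets],
    )


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def imu_forward_model(traj: Trajectory, spec: TrialSpec | None = None
                      ) -> ImuTrial:
    """Sample the trajectory through the IMU measurement model.

    Sensor-frame specific force = R(t)^T (a_earth + g e_z) / g  [in g units],
    with R(t) the scripted wrist rotation about the sensor x-axis, plus the
    constant accelerometer bias and seeded Gaussian noise; angular velocity
    is the scripted rotation rate plus noise. Samples are clipped to the
    device ranges (+/-4 g, +/-500 deg/s).
    """
    spec = spec or traj.spec
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(_IMU_STREAM,)))
    n = int(np.floor(traj.total_duration * spec.imu_rate)) + 1
    t = np.arange(n) / spec.imu_rate

    a_e = traj.acceleration(t)  # m/s^2
    theta = np.deg2rad(traj.wrist_angle_deg(t))
    rate_dps = traj.wrist_rate_dps(t)
    if np.max(np.abs(rate_dps)) > GYRO_RANGE_DPS:
        warnings.warn(
            "scripted rotation rate exceeds the +/-500 deg/s gyro range; "
            "samples will be clipped", stacklevel=2)

    # specific force in g, earth frame
    f = a_e / GRAVITY
    f[:, 2] += 1.0
    # rotate into the sensor frame: R^T for a rotation about x
    c, s = np.cos(theta), np.sin(theta)
    acc = np.empty_like(f)
    acc[:, 0] = f[:, 0]
    acc[:, 1] = c * f[:, 1] + s * f[:, 2]
    acc[:, 2] = -s * f[:, 1] + c * f[:, 2]

    acc += np.asarray(spec.accel_bias)
    if spec.accel_noise_sd > 0:
        acc += rng.normal(0.0, spec.accel_noise_sd, acc.shape)
    acc = np.clip(acc, -ACCEL_RANGE_G, ACCEL_RANGE_G)

    gyr = np.zeros((n, 3))
    gyr[:, 0] = rate_dps
    if spec.gyro_noise_sd > 0:
        gyr += rng.normal(0.0, spec.gyro_noise_sd, gyr.shape)
    gyr = np.clip(gyr, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)

    return ImuTrial(t=t, acc=acc, gyr=gyr, rate=spec.imu_rate,
                    task=spec.task, trial_id=spec.trial_id)


def marker_forward_model(traj: Trajectory, spec: TrialSpec | None = None,
                         gaps: list | None = None) -> MarkerTrial:
    """Sample the trajectory as a noisy optical marker track in mm.

    `gaps` is an optional list of (start_index, n_frames) occlusions to
    inject; each must be shorter than 10 frames (longer gaps are outside
    what the reference pipeline will interpolate and are rejected here).
    """
    spec = spec or traj.spec
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(_MARKER_STREAM,)))
    n = int(np.floor(traj.total_duration * spec.marker_rate)) + 1
    t = np.arange(n) / spec.marker_rate
    pos = traj.position(t) * 1000.0  # mm
    if spec.marker_noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.marker_noise_sd, pos.shape)
    if gaps:
        for start, length in gaps:
            if length >= 10:
                raise ValueError(
                    f"injected gap of {length} frames: only gaps of <10 "
                    "frames are representable (longer gaps make the trial "
                    "unprocessable)")
            pos[start:start + length] = np.nan
    return MarkerTrial(t=t, pos=pos, rate=spec.marker_rate, task=spec.task,
                       trial_id=spec.trial_id)


def simulate_pair(spec: TrialSpec, gaps: list | None = None):
    """Convenience: (ImuTrial, MarkerTrial, GroundTruth) for one spec."""
    traj = compose_trajectory(spec)
    return (imu_forward_model(traj, spec),
            marker_forward_model(traj, spec, gaps=gaps),
            traj.ground_truth)


# ---------------------------------------------------------------------------
# default task scripts
# ---------------------------------------------------------------------------
# Amplitudes (m), durations (s), dwells (s) and wrist rotations (deg) are
# scripted so that movement times and peak speeds fall in the range typical
# of seated reach-manipulate-return tasks (block to a 37 cm shelf 25 cm
# away; drink and pour travel distances are plausible constants, not
# measured values). Rotations sum to zero so every trial ends pronated.

_TASK_SEGMENTS = {
    "block": (
        SegmentSpec((0.30, 0.0, 0.0), 0.70, 0.35, rotation_deg=25.0),
        SegmentSpec((0.25, 0.0, 0.37), 0.70, 0.35, rotation_deg=15.0),
        SegmentSpec((-0.55, 0.0, -0.37), 1.05, 0.0, rotation_deg=-40.0),
    ),
    "drink": (
        SegmentSpec((0.25, 0.0, 0.0), 0.85, 0.50, rotation_deg=30.0),
        SegmentSpec((-0.10, -0.05, 0.35), 0.95, 0.80, rotation_deg=35.0),
        SegmentSpec((-0.15, 0.05, -0.35), 1.10, 0.0, rotation_deg=-65.0),
    ),
    "pour": (
        SegmentSpec((0.25, 0.0, 0.0), 0.80, 0.35, rotation_deg=30.0),
        SegmentSpec((0.05, -0.15, 0.15), 0.85, 0.55, rotation_deg=70.0),
        SegmentSpec((-0.05, 0.15, -0.15), 0.85, 0.35, rotation_deg=-70.0),
        SegmentSpec((-0.25, 0.0, 0.0), 0.95, 0.0, rotation_deg=-30.0),
    ),
}


def default_trial_spec(task: str, seed: int, **overrides) -> TrialSpec:
    """The canonical scripted trial for a task (no between-trial jitter)."""
    if task not in _TASK_SEGMENTS:
        raise ValueError(f"unknown task {task!r}")
    kw = dict(task=task, segments=_TASK_SEGMENTS[task], seed=seed,
              trial_id=f"{task}_{seed:04d}")
    kw.update(overrides)
    return TrialSpec(**kw)


def sample_trial_spec(task: str, rng: np.random.Generator,
                      trial_id: str = "", **overrides) -> TrialSpec:
    """Draw one trial with realistic between-trial variability.

    Emulates the spread across participants and repetitions: a global tempo
    factor (+/-15%), per-segment duration jitter (8% lognormal), dwell
    scaling (+/-25%) and a global amplitude factor (+/-10%, preserving
    return-to-start closure). Rotations scale with amplitude so they still
    sum to zero.
    """
    base = _TASK_SEGMENTS[task]
    tempo = rng.uniform(0.85, 1.15)
    amp_scale = rng.uniform(0.90, 1.10)
    segments = []
    for seg in base:
        dur = seg.duration * tempo * np.exp(rng.normal(0.0, 0.08))
        dwell = seg.dwell_after * rng.uniform(0.75, 1.25)
        amp = tuple(a * amp_scale for a in seg.amplitude)
        segments.append(SegmentSpec(amp, dur, dwell,
                                    rotation_deg=seg.rotation_deg * amp_scale))
    seed = int(rng.integers(0, 2**31 - 1))
    kw = dict(task=task, segments=tuple(segments), seed=seed,
              trial_id=trial_id or f"{task}_{seed:09d}")
    kw.update(overrides)
    return TrialSpec(**kw)
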