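"""Core in-memory containers shared across the pipeline.

Conventions: accelerometer samples are stored in g, gyroscope samples in
deg/s, marker positions in mm, velocities in m/s, times in seconds from
trial start. Arrays are NumPy float64; missing marker samples are NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import TrialValidationError

TASKS = ("block", "drink", "pour")

#: Expected number of velocity peaks per task (reach / manipulate / return
#: structure; the pour task has an extra pouring sub-movement).
EXPECTED_PEAKS = {"block": 3, "drink": 3, "pour": 4}

ACCEL_RANGE_G = 4.0
GYRO_RANGE_DPS = 500.0
GRAVITY = 9.81  # m/s^2, exact by convention in this package


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class ImuTrial:
    """One wrist-IMU recording: time, 3-axis accel (g), 3-axis gyro (deg/s)."""

    t: np.ndarray
    acc: np.ndarray  # (n, 3) in g
    gyr: np.ndarray  # (n, 3) in deg/s
    rate: float
    task: str
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.acc = _as_f64(self.acc)
        self.gyr = _as_f64(self.gyr)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, rate_tolerance: float = 0.01) -> None:
        """Check structural and range invariants; raise TrialValidationError."""
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: acc/gyr shape must be (n, 3) with n={n}"
            )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            bad = np.where(np.diff(self.t) <= 0)[0]
            raise TrialValidationError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing "
                f"at rows {bad[:10].tolist()}"
            )
        if self.task not in TASKS:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: unknown task {self.task!r}"
            )
        bad_a = np.where(np.any(np.abs(self.acc) > ACCEL_RANGE_G, axis=1))[0]
        if bad_a.size:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: accelerometer out of +/-{ACCEL_RANGE_G} g "
                f"range at rows {bad_a[:10].tolist()}"
            )
        bad_g = np.where(np.any(np.abs(self.gyr) > GYRO_RANGE_DPS, axis=1))[0]
        if bad_g.size:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: gyroscope out of +/-{GYRO_RANGE_DPS} deg/s "
                f"range at rows {bad_g[:10].tolist()}"
            )
        if rate_tolerance is not None and abs(self.rate - 100.0) > 100.0 * rate_tolerance:
            # nominal 100 Hz device; overridable by passing rate_tolerance=None
            raise TrialValidationError(
                f"trial {self.trial_id!r}: rate {self.rate} Hz departs from the "
                f"nominal 100 Hz by more than {100 * rate_tolerance:.0f}%"
            )

    def slice(self, start: int, stop: int) -> "ImuTrial":
        return ImuTrial(
            t=self.t[start:stop],
            acc=self.acc[start:stop],
            gyr=self.gyr[start:stop],
            rate=self.rate,
            task=self.task,
            trial_id=self.trial_id,
        )

    @property
    def gyro_speed(self) -> np.ndarray:
        """Resultant angular speed (deg/s) per sample."""
        return np.linalg.norm(self.gyr, axis=1)


@dataclass
class MarkerTrial:
    """One optical wrist-marker recording: time and 3-D position in mm.

    Missing samples (marker occlusions) are NaN in all three coordinates.
    """

    t: np.ndarray
    pos: np.ndarray  # (n, 3) in mm, NaN = missing
    rate: float
    task: str
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.pos = _as_f64(self.pos)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = len(self.t)
        if self.pos.shape != (n, 3):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: pos shape must be (n, 3) with n={n}"
            )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing"
            )
        if self.task not in TASKS:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: unknown task {self.task!r}"
            )

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the sample is missing."""
        return np.any(np.isnan(self.pos), axis=1)


@dataclass
class VelocityProfile:
    """Resultant (speed) profile in m/s with provenance."""

    v: np.ndarray
    t: np.ndarray
    rate: float
    source: str  # "imu" | "reference"

    def __post_init__(self) -> None:
        self.v = _as_f64(self.v)
        self.t = _as_f64(self.t)

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class TrialMetrics:
    """The three clinical metrics for one trial from one system."""

    trial_id: str
    task: str
    source: str
    movement_time_ms: float
    peak_velocity_ms: float  # m/s
    sparc: float
    onset_idx: int
    offset_idx: int
    n_peaks_found: int
    peak_threshold: float = float("nan")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Exact kinematic truth for one simulated trial."""

    movement_time_ms: float
    peak_velocity_ms: float
    sparc: float
    onset_s: float
    offset_s: float
    segment_onsets_s: list = field(default_factory=list)
    segment_offsets_s: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)
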