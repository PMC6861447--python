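"""Pipeline configuration: every threshold used anywhere in the chain.

Defaults follow the processing rules of the validation protocol this package
implements (trim margins, angular-speed thresholds, onset/offset fractions,
peak-iteration schedule); parameters the protocol leaves open (AHRS gain,
stationary-envelope threshold, SPARC band) carry documented defaults and are
all overridable from a YAML file so a report can be reproduced bit-for-bit
from its serialized configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError
from .types import EXPECTED_PEAKS


@dataclass
class PipelineConfig:
    # --- orientation (AHRS) ---
    #: Madgwick gradient-descent gain; 0.1 is the standard all-round value.
    beta: float = 0.1
    #: Frames of the assumed-stationary lead-in used to initialize tilt.
    init_window_frames: int = 100
    #: Acceleration rejection: skip the accelerometer correction when the
    #: measured magnitude departs from 1 g by more than this (g); 0 disables.
    accel_reject_g: float = 0.1
    #: Also reject the correction while the smoothed angular speed exceeds
    #: this (deg/s); 0 disables.
    ahrs_gyro_gate_dps: float = 10.0
    #: ... or while the band-passed (0.2-3 Hz) acceleration energy exceeds
    #: this (g); catches horizontal reaches the magnitude test cannot see.
    ahrs_accel_dyn_gate_g: float = 0.04

    # --- trial trimming ---
    #: Movement-start predicate: angular speed above this (deg/s) ...
    start_gyro_thresh_dps: float = 10.0
    #: ... or gravity-compensated earth-frame |z accel| above this (g) ...
    z_accel_thresh_g: float = 0.7
    #: ... or provisional resultant velocity above this (m/s).
    start_velocity_thresh_ms: float = 0.1
    #: Movement-end predicate uses a laxer gyro and velocity threshold
    #: (the sensor is harder to keep perfectly still when set down).
    end_gyro_thresh_dps: float = 5.0
    end_velocity_thresh_ms: float = 0.0025
    #: Stationary margin retained on either side of the detected movement.
    trim_margin_frames: int = 100

    # --- stationary detection ---
    hp_cutoff_hz: float = 0.001
    lp_cutoff_hz: float = 2.0
    filter_order: int = 2
    #: Minimum threshold on the filtered acceleration envelope (g) at or
    #: above which the sensor counts as moving.
    stationary_env_thresh_g: float = 0.05
    #: The working threshold adapts to the sensor: max(minimum threshold,
    #: envelope noise floor + this margin). Slow movements that stay under
    #: it are caught by the angular-speed criterion.
    stationary_env_margin_g: float = 0.06
    #: Angular-speed criterion feeding the stationary mask (deg/s).
    stationary_gyro_thresh_dps: float = 10.0
    #: Runs (of either label) shorter than this (s) are absorbed, so a
    #: mid-reach dip of |a| through zero cannot split a movement.
    min_stationary_run_s: float = 0.15
    #: Movement intervals are widened by this margin (s) so the
    #: zero-velocity anchors fall inside true rest.
    zupt_margin_s: float = 0.10

    # --- start/center/end sectioning ---
    center_gyro_thresh_dps: float = 10.0
    center_start_run_frames: int = 10
    center_end_run_frames: int = 20

    # --- dead reckoning ---
    drift_model: str = "linear"  # "linear" | "none"

    # --- reference (marker) pipeline ---
    #: Target predicted mean squared residual of the position smoother (mm^2).
    target_mse_mm2: float = 5.0

    # --- peak detection ---
    peak_init_thresh_ms: float = 0.1
    peak_thresh_factor: float = 1.05
    peak_max_iter: int = 60
    #: Local maxima closer than this (s) are merged, keeping the highest.
    peak_min_separation_s: float = 0.30

    # --- onset / offset ---
    onset_frac_imu: float = 0.01
    onset_frac_ref: float = 0.02
    offset_frac: float = 0.02
    onset_window_frames: int = 50
    offset_window_frames: int = 75
    quiet_thresh_ms: float = 0.05

    # --- SPARC ---
    sparc_fc_hz: float = 20.0
    sparc_amp_thresh: float = 0.05
    sparc_pad_factor: int = 16

    # --- tasks ---
    expected_peaks: dict = field(default_factory=lambda: dict(EXPECTED_PEAKS))

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()
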