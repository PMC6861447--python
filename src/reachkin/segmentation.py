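"""Trial trimming, stationary detection and start/center/end sectioning.

The trimming and sectioning rules mirror the wearable pipeline's protocol:
a trial is cut to 100 frames either side of the detected movement; a
filtered acceleration envelope classifies each sample as stationary or
moving (feeding the zero-velocity updates downstream); and sustained runs
of angular speed delimit the center section actually analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import NoMovementError, TrialValidationError
from .types import GRAVITY, ImuTrial


@dataclass
class SectionBounds:
    """Sample-index bounds (0-based, half-open) of the analysed sections."""

    trim_start: int
    trim_end: int
    center_start: int = -1
    center_end: int = -1

    def validate(self) -> None:
        ok = (self.trim_start <= self.center_start < self.center_end
              <= self.trim_end)
        if not ok:
            raise TrialValidationError(
                f"inconsistent section bounds {self}")


def velocity_preview(a_e: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Provisional resultant speed (m/s) for the trim predicates.

    Naive per-axis integration of the earth-frame acceleration with the
    end-to-end linear drift removed (the trial is assumed to start and end
    at rest). This is only used to decide *where* movement is; the
    drift-corrected profile is computed later on the trimmed trial.
    """
    v = integrate.cumulative_trapezoid(a_e, t, axis=0, initial=0.0)
    if len(t) > 1 and t[-1] > t[0]:
        frac = ((t - t[0]) / (t[-1] - t[0]))[:, None]
        v = v - frac * v[-1]
    return np.linalg.norm(v, axis=1)


def trim_trial(trial: ImuTrial, a_e: np.ndarray,
               preview: np.ndarray | None = None,
               config: PipelineConfig = DEFAULT_CONFIG) -> SectionBounds:
    """Locate the movement and keep a 100-frame stationary margin around it.

    Movement start: angular speed > 10 deg/s, or gravity-compensated
    earth-frame |z| acceleration > 0.7 g, or provisional resultant velocity
    > 0.1 m/s. Movement end uses the laxer 5 deg/s and 0.0025 m/s values.
    """
    if preview is None:
        preview = velocity_preview(a_e, trial.t)
    gyro_speed = trial.gyro_speed
    z_crit = np.abs(a_e[:, 2]) > config.z_accel_thresh_g * GRAVITY

    start_pred = ((gyro_speed > config.start_gyro_thresh_dps) | z_crit
                  | (preview > config.start_velocity_thresh_ms))
    end_pred = ((gyro_speed > config.end_gyro_thresh_dps) | z_crit
                | (preview > config.end_velocity_thresh_ms))

    start_hits = np.flatnonzero(start_pred)
    if start_hits.size == 0:
        raise NoMovementError(
            f"trial {trial.trial_id!r}: no sample satisfies the "
            "movement-start predicate")
    end_hits = np.flatnonzero(end_pred)
    first = int(start_hits[0])
    last = int(end_hits[-1])  # end predicate is a superset of start's
    trim_start = max(first - config.trim_margin_frames, 0)
    trim_end = min(last + config.trim_margin_frames + 1, len(trial))
    return SectionBounds(trim_start=trim_start, trim_end=trim_end)


def stationary_mask(a_e: np.ndarray, rate: float,
                    config: PipelineConfig = DEFAULT_CONFIG,
                    gyro_speed: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask, True where the sensor is stationary.

    Envelope = lowpass(|highpass(||a||, 0.001 Hz)|, 2 Hz), both Butterworth
    and zero-phase (forward-backward); a sample is moving where the envelope
    (in g) reaches the threshold. When `gyro_speed` (deg/s) is supplied, a
    sample is also moving where its zero-phase-smoothed angular speed
    reaches the stationary gyro threshold: wrist transport always rotates
    the forearm, and the rotation channel stays readable when a slow reach's
    acceleration hides under the rectified noise floor of the envelope.

    Runs of either label shorter than `min_stationary_run_s` are absorbed
    into their surroundings (movements last far longer, and the mid-reach
    zero-crossing of acceleration must not split a movement interval).
    """
    n = len(a_e)
    if n < rate:  # filter warm-up
        raise TrialValidationError(
            f"trial of {n} samples at {rate} Hz is shorter than the 1 s "
            "filter warm-up")
    mag_g = np.linalg.norm(a_e, axis=1) / GRAVITY
    nyq = rate / 2.0
    sos_hp = signal.butter(config.filter_order, config.hp_cutoff_hz / nyq,
                           btype="highpass", output="sos")
    sos_lp = signal.butter(config.filter_order, config.lp_cutoff_hz / nyq,
                           btype="lowpass", output="sos")
    hp = signal.sosfiltfilt(sos_hp, mag_g)
    env = signal.sosfiltfilt(sos_lp, np.abs(hp))
    # noise-adaptive threshold: rest dominates a trial, so the median of
    # the envelope estimates the rectified-noise floor; the margin keeps
    # the threshold above the floor's flicker at any sensor noise level
    floor = float(np.median(env))
    thresh = max(config.stationary_env_thresh_g,
                 floor + config.stationary_env_margin_g)
    moving = env >= thresh
    if gyro_speed is not None:
        gyro_env = signal.sosfiltfilt(sos_lp, np.asarray(gyro_speed,
                                                         dtype=np.float64))
        moving |= gyro_env >= config.stationary_gyro_thresh_dps

    min_run = int(round(config.min_stationary_run_s * rate))
    if min_run > 1:
        for start, stop in _runs(moving):  # noise blips -> stationary
            if stop - start < min_run:
                moving[start:stop] = False
        mask = ~moving
        for start, stop in _runs(mask):  # short dips -> still moving
            if stop - start < min_run:
                mask[start:stop] = False
    else:
        mask = ~moving

    # Dilate movement intervals so the zero-velocity anchors sit in true
    # rest (the smoothed detectors release a beat after motion begins). A
    # stationary run squeezed out by the dilation keeps its center sample:
    # the wrist is genuinely at rest mid-dwell, and that pin preserves the
    # per-segment drift correction.
    d = int(round(config.zupt_margin_s * rate))
    if d > 0 and not mask.all():
        eroded = np.zeros_like(mask)
        for start, stop in _runs(mask):
            lo = start if start == 0 else start + d
            hi = stop if stop == n else stop - d
            if lo < hi:
                eroded[lo:hi] = True
            else:
                center = (start + stop) // 2
                eroded[center] = True
        mask = eroded
    return mask


def _runs(mask: np.ndarray):
    """(start, stop) half-open index pairs of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))
                                 .astype(np.int8)))
    return list(zip(idx[0::2], idx[1::2]))


def split_sections(trial: ImuTrial, bounds: SectionBounds,
                   config: PipelineConfig = DEFAULT_CONFIG) -> SectionBounds:
    """Delimit the center section from sustained angular-speed runs.

    center_start begins the first run of >= 10 consecutive frames with
    angular speed above 10 deg/s; center_end closes the last run of >= 20
    such frames (the longer end requirement guards against the vibration of
    setting the sensor down). Indices are absolute into the untrimmed trial.
    """
    gyro_speed = trial.gyro_speed[bounds.trim_start:bounds.trim_end]
    above = gyro_speed > config.center_gyro_thresh_dps
    runs = _runs(above)
    start_runs = [r for r in runs
                  if r[1] - r[0] >= config.center_start_run_frames]
    end_runs = [r for r in runs
                if r[1] - r[0] >= config.center_end_run_frames]
    if not start_runs or not end_runs:
        raise NoMovementError(
            f"trial {trial.trial_id!r}: no sustained angular-speed run "
            f"(need {config.center_start_run_frames} frames above "
            f"{config.center_gyro_thresh_dps} deg/s)")
    center_start = bounds.trim_start + int(start_runs[0][0])
    center_end = bounds.trim_start + int(end_runs[-1][1])
    out = SectionBounds(trim_start=bounds.trim_start,
                        trim_end=bounds.trim_end,
                        center_start=center_start,
                        center_end=center_end)
    out.validate()
    return out
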