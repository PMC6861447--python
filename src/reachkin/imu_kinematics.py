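"""Zero-velocity-update (ZUPT) dead reckoning to a resultant speed profile.

Velocity comes from trapezoidal integration of earth-frame acceleration
inside each movement interval; because the wrist is known to be at rest on
either side, the residual end-of-interval velocity is pure integration
drift and is removed by subtracting a linear-in-time ramp (the standard
ZUPT drift model). Stationary samples are pinned to exactly zero.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import TrialValidationError
from .segmentation import _runs
from .types import VelocityProfile


def integrate_velocity(a_e: np.ndarray, mask: np.ndarray, t: np.ndarray,
                       rate: float,
                       config: PipelineConfig = DEFAULT_CONFIG,
                       ) -> VelocityProfile:
    """Drift-corrected resultant speed (m/s) from earth-frame acceleration.

    Parameters
    ----------
    a_e : (n, 3) earth-frame acceleration, gravity removed, m/s^2.
    mask : (n,) stationary mask (True = at rest).
    t : (n,) timestamps, s.
    rate : nominal sampling rate for the returned profile.

    Each contiguous non-stationary interval must be bounded by stationary
    samples on both sides; a trial that starts or ends mid-movement raises.
    Drift correction is applied per axis before taking the Euclidean norm
    (correcting the norm itself would bias speed upward).
    """
    a_e = np.asarray(a_e, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    t = np.asarray(t, dtype=np.float64)
    n = len(t)
    if a_e.shape[0] != n or mask.shape[0] != n:
        raise TrialValidationError("a_e, mask and t must share their length")

    v = np.zeros((n, 3))
    for start, stop in _runs(~mask):
        if start == 0 or stop == n:
            raise TrialValidationError(
                "movement interval not bounded by stationary samples on "
                "both sides (trial starts or ends mid-movement)")
        lo, hi = start - 1, stop  # stationary anchors, inclusive
        seg_t = t[lo:hi + 1]
        seg_v = integrate.cumulative_trapezoid(a_e[lo:hi + 1], seg_t,
                                               axis=0, initial=0.0)
        if config.drift_model == "linear":
            ramp = ((seg_t - seg_t[0]) / (seg_t[-1] - seg_t[0]))[:, None]
            seg_v = seg_v - ramp * seg_v[-1]
        elif config.drift_model != "none":
            raise ValueError(f"unknown drift model {config.drift_model!r}")
        v[start:stop] = seg_v[1:-1]

    v[mask] = 0.0
    return VelocityProfile(v=np.linalg.norm(v, axis=1), t=t, rate=rate,
                           source="imu")
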