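"""Clinical metrics on a resultant speed profile.

Peak detection with the iterated-threshold rule, velocity-fraction
onset/offset events, and the three outcome measures: movement time, peak
velocity and spectral arc length (SPARC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import NoMovementError, UndefinedMetricError
from .types import TrialMetrics, VelocityProfile


@dataclass
class SparcParams:
    """Spectral arc length parameters (adaptive-cutoff formulation)."""

    freq_cutoff: float = 20.0  # Hz, hard upper band edge
    amplitude_threshold: float = 0.05  # fraction of the 0 Hz magnitude
    pad_factor: int = 16  # zero-pad to next power of two >= this x length

    def __post_init__(self):
        if self.freq_cutoff <= 0:
            raise ValueError("freq_cutoff must be positive")
        if not 0 < self.amplitude_threshold < 1:
            raise ValueError("amplitude_threshold must be in (0, 1)")


@dataclass
class PeakResult:
    indices: np.ndarray
    threshold: float
    matched: bool  # True if the expected count was hit exactly


def local_maxima(v: np.ndarray) -> np.ndarray:
    """Strict local maxima; a plateau peak yields its first sample."""
    v = np.asarray(v, dtype=np.float64)
    n = len(v)
    out = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(out, dtype=int)


def _merge_close(v: np.ndarray, idx: np.ndarray, min_sep: int) -> np.ndarray:
    """Merge maxima closer than min_sep samples, keeping the highest."""
    if len(idx) <= 1 or min_sep <= 1:
        return idx
    kept: list[int] = []
    for i in idx:
        if kept and i - kept[-1] < min_sep:
            if v[i] > v[kept[-1]]:
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return np.array(kept, dtype=int)


def _peaks_above(v, thr, min_sep) -> np.ndarray:
    idx = local_maxima(v)
    idx = idx[v[idx] > thr]
    return _merge_close(v, idx, min_sep)


def _threshold_schedule(config: PipelineConfig) -> np.ndarray:
    return (config.peak_init_thresh_ms
            * config.peak_thresh_factor ** np.arange(config.peak_max_iter))


def detect_peaks(profile: VelocityProfile, expected_n: int,
                 config: PipelineConfig = DEFAULT_CONFIG) -> PeakResult:
    """Find the task's expected number of speed peaks.

    Starting from the minimum plausible peak height (0.1 m/s) the threshold
    is raised by a factor of 1.05 for up to 60 iterations; the peak set at
    the first threshold yielding exactly `expected_n` local maxima is
    returned. If no threshold is exact, the best singleton match (count
    closest to expected at the largest such threshold) is returned with a
    warning; pair the two systems through :func:`detect_peaks_paired` when
    both profiles are available.
    """
    v = profile.v
    min_sep = max(int(round(config.peak_min_separation_s * profile.rate)), 1)
    best = None  # (count_gap, -threshold, idx, thr)
    for thr in _threshold_schedule(config):
        idx = _peaks_above(v, thr, min_sep)
        if len(idx) == 0:
            if best is None:
                raise NoMovementError(
                    "no speed peak above the minimum threshold "
                    f"({config.peak_init_thresh_ms} m/s)")
            break
        if len(idx) == expected_n:
            return PeakResult(indices=idx, threshold=float(thr), matched=True)
        key = (abs(len(idx) - expected_n), -thr)
        if best is None or key <= best[0]:
            best = (key, idx, float(thr))
    if best is None:
        raise NoMovementError(
            "no speed peak above the minimum threshold "
            f"({config.peak_init_thresh_ms} m/s)")
    warnings.warn(
        f"expected {expected_n} peaks never matched exactly; using "
        f"{len(best[1])} peaks at threshold {best[2]:.3f} m/s", stacklevel=2)
    return PeakResult(indices=best[1], threshold=best[2], matched=False)


def detect_peaks_paired(imu: VelocityProfile, ref: VelocityProfile,
                        expected_n: int,
                        config: PipelineConfig = DEFAULT_CONFIG
                        ) -> tuple[PeakResult, PeakResult]:
    """Joint fallback: both systems at the same threshold.

    Each profile is first searched for an exact match of the expected count.
    When either fails, the largest threshold at which both systems detect
    the *same* number of peaks is used for both (the protocol's rule for
    the rare non-matching trial).
    """
    r_imu = _try_detect(imu, expected_n, config)
    r_ref = _try_detect(ref, expected_n, config)
    if r_imu is not None and r_ref is not None:
        return r_imu, r_ref

    sep_i = max(int(round(config.peak_min_separation_s * imu.rate)), 1)
    sep_r = max(int(round(config.peak_min_separation_s * ref.rate)), 1)
    fallback = None
    for thr in _threshold_schedule(config):
        pi = _peaks_above(imu.v, thr, sep_i)
        pr = _peaks_above(ref.v, thr, sep_r)
        if len(pi) == 0 or len(pr) == 0:
            break
        if len(pi) == len(pr):
            fallback = (pi, pr, float(thr))
    if fallback is None:
        raise NoMovementError(
            "no threshold yields a common peak count for the two systems")
    pi, pr, thr = fallback
    return (PeakResult(pi, thr, matched=len(pi) == expected_n),
            PeakResult(pr, thr, matched=len(pr) == expected_n))


def _try_detect(profile, expected_n, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = detect_peaks(profile, expected_n, config)
    return res if res.matched else None


# ---------------------------------------------------------------------------
# onset / offset
# ---------------------------------------------------------------------------

def find_onset(profile: VelocityProfile, first_peak: int,
               config: PipelineConfig = DEFAULT_CONFIG) -> int:
    """Movement onset: first threshold crossing with a quiet lead-in.

    The threshold is a fraction of the first peak's speed (1% for the IMU,
    2% for the reference — the IMU's ZUPT-pinned profile tolerates the
    lower value); the crossing must additionally be preceded by 50 frames
    averaging below 0.05 m/s. Candidates are scanned from the earliest
    crossing; if none has a quiet lead-in, the crossing nearest the peak is
    used with a warning.
    """
    frac = (config.onset_frac_imu if profile.source == "imu"
            else config.onset_frac_ref)
    thr = frac * profile.v[first_peak]
    v = profile.v
    # walk backward from the peak: onset begins the suprathreshold run
    # that culminates in the first peak (earlier blips are not the rise)
    i = first_peak
    while i > 0 and v[i - 1] >= thr:
        i -= 1
    if i == 0 and v[0] >= thr:
        warnings.warn("speed never drops below the onset threshold before "
                      "the first peak; using the profile start", stacklevel=2)
        return 0
    lead = v[max(0, i - config.onset_window_frames):i]
    if lead.size and lead.mean() >= config.quiet_thresh_ms:
        warnings.warn(
            "lead-in before the onset is not quiet (mean "
            f"{lead.mean():.3f} m/s); keeping the threshold-only crossing",
            stacklevel=2)
    return i


def find_offset(profile: VelocityProfile, last_peak: int,
                config: PipelineConfig = DEFAULT_CONFIG) -> int:
    """Movement offset: mirror of :func:`find_onset`.

    First drop below 2% of the last peak followed by 75 frames averaging
    below 0.05 m/s.
    """
    thr = config.offset_frac * profile.v[last_peak]
    v = profile.v
    n = len(v)
    j = last_peak
    while j < n - 1 and v[j + 1] > thr:
        j += 1
    if j == n - 1 and v[j] > thr:
        warnings.warn("speed never drops below the offset threshold after "
                      "the last peak; using the profile end", stacklevel=2)
        return n - 1
    j = min(j + 1, n - 1)  # first sample at or below the threshold
    trail = v[j + 1:j + 1 + config.offset_window_frames]
    if trail.size and trail.mean() >= config.quiet_thresh_ms:
        warnings.warn(
            "tail after the offset is not quiet (mean "
            f"{trail.mean():.3f} m/s); keeping the threshold-only crossing",
            stacklevel=2)
    return j


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def movement_time(onset_idx: int, offset_idx: int, rate: float) -> float:
    """Movement time in ms between onset and offset sample indices."""
    return (offset_idx - onset_idx) / rate * 1000.0


def peak_velocity(v: np.ndarray, onset_idx: int, offset_idx: int) -> float:
    """Highest point of the resultant speed curve within [onset, offset]."""
    window = np.asarray(v)[onset_idx:offset_idx + 1]
    if window.size == 0:
        raise UndefinedMetricError("empty onset-offset window")
    return float(window.max())


def sparc(v: np.ndarray, rate: float,
          params: SparcParams | None = None) -> float:
    """Spectral arc length of a speed profile (dimensionless, <= 0).

    Negative arc length of the normalized Fourier magnitude spectrum over
    [0, omega_c], where omega_c adapts to the highest frequency (below the
    hard cutoff) still carrying at least `amplitude_threshold` of the DC
    magnitude. More negative = less smooth. Invariant to amplitude scaling
    and time shifts of the cropped profile.
    """
    params = params or SparcParams()
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0 or not np.any(v != 0):
        raise UndefinedMetricError("SPARC undefined for an all-zero profile")
    nfft = 1 << int(np.ceil(np.log2(max(params.pad_factor * len(v), 2))))
    mag = np.abs(np.fft.rfft(v, nfft))
    freq = np.fft.rfftfreq(nfft, d=1.0 / rate)
    mag = mag / mag[0]

    f_sel, m_sel, omega_c = _sparc_band(freq, mag, params)
    df = np.diff(f_sel)
    dm = np.diff(m_sel)
    return float(-np.sum(np.sqrt((df / omega_c) ** 2 + dm**2)))


def _sparc_band(freq, mag, params: SparcParams):
    """Adaptive frequency band [0, omega_c] of the normalized spectrum.

    omega_c is the highest in-band frequency still carrying
    `amplitude_threshold` of the DC magnitude; the exact crossing is placed
    by linear interpolation between bins so the band edge does not jump
    with the FFT grid.
    """
    in_band = freq <= params.freq_cutoff
    f_band, m_band = freq[in_band], mag[in_band]
    th = params.amplitude_threshold
    above = np.flatnonzero(m_band >= th)
    # DC is always >= threshold, so `above` is non-empty
    i = above[-1]
    if i + 1 < len(f_band) and m_band[i] > th:
        # sub-bin interpolation of the threshold crossing
        frac = (m_band[i] - th) / (m_band[i] - m_band[i + 1])
        omega_c = f_band[i] + frac * (f_band[i + 1] - f_band[i])
        f_sel = np.append(f_band[:i + 1], omega_c)
        m_sel = np.append(m_band[:i + 1], th)
    else:
        omega_c = f_band[i]
        f_sel, m_sel = f_band[:i + 1], m_band[:i + 1]
    if omega_c <= 0:  # spectrum collapses onto DC; take the full band
        omega_c = f_band[-1]
        f_sel, m_sel = f_band, m_band
    return f_sel, m_sel, omega_c


def compute_trial_metrics(profile: VelocityProfile, expected_n: int,
                          task: str, trial_id: str,
                          config: PipelineConfig = DEFAULT_CONFIG,
                          peaks: PeakResult | None = None,
                          sparc_params: SparcParams | None = None,
                          ) -> TrialMetrics:
    """All three metrics for one profile (peaks may be precomputed)."""
    if peaks is None:
        peaks = detect_peaks(profile, expected_n, config)
    onset = find_onset(profile, int(peaks.indices[0]), config)
    offset = find_offset(profile, int(peaks.indices[-1]), config)
    if sparc_params is None:
        sparc_params = SparcParams(freq_cutoff=config.sparc_fc_hz,
                                   amplitude_threshold=config.sparc_amp_thresh,
                                   pad_factor=config.sparc_pad_factor)
    return TrialMetrics(
        trial_id=trial_id,
        task=task,
        source=profile.source,
        movement_time_ms=movement_time(onset, offset, profile.rate),
        peak_velocity_ms=peak_velocity(profile.v, onset, offset),
        sparc=sparc(profile.v[onset:offset + 1], profile.rate, sparc_params),
        onset_idx=onset,
        offset_idx=offset,
        n_peaks_found=len(peaks.indices),
        peak_threshold=peaks.threshold,
    )
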