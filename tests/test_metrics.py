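"""Peak detection, onset/offset events, and the three clinical metrics."""

import warnings

import numpy as np
import pytest

import reachkin as rk
from reachkin.config import PipelineConfig
from reachkin.errors import NoMovementError, UndefinedMetricError
from reachkin.metrics import (SparcParams, detect_peaks, detect_peaks_paired,
                              find_offset, find_onset, local_maxima,
                              movement_time, peak_velocity, sparc)
from reachkin.synthetic import minimum_jerk_velocity
from reachkin.types import VelocityProfile


def _profile(v, rate=100.0, source="imu"):
    v = np.asarray(v, dtype=float)
    return VelocityProfile(v=v, t=np.arange(len(v)) / rate, rate=rate,
                           source=source)


def _pulse_train(centers, heights, rate=100.0, width=0.6, total=8.0):
    """Speed profile of separated minimum-jerk pulses (analytic)."""
    t = np.arange(int(total * rate) + 1) / rate
    v = np.zeros_like(t)
    for c, h in zip(centers, heights):
        seg = (t >= c - width / 2) & (t <= c + width / 2)
        d = h * width / 1.875
        v[seg] = np.abs(minimum_jerk_velocity(d, width,
                                              t[seg] - (c - width / 2)))
    return _profile(v, rate)


def brute_force_peaks(v, threshold):
    """Independent exhaustive strict-local-maximum scan."""
    return [i for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] > threshold]


class TestLocalMaxima:
    def test_matches_exhaustive_scan_on_random_data(self):
        rng = np.random.default_rng(0)
        v = rng.random(500)
        assert local_maxima(v).tolist() == brute_force_peaks(v, -np.inf)

    def test_plateau_takes_first_sample(self):
        v = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        assert local_maxima(v).tolist() == [2]


class TestDetectPeaks:
    def test_three_pulses_found_and_match_oracle(self):
        prof = _pulse_train([1.5, 3.5, 5.5], [0.8, 1.1, 0.9])
        res = detect_peaks(prof, 3)
        assert res.matched
        assert res.indices.tolist() == brute_force_peaks(prof.v,
                                                         res.threshold)

    def test_flat_zero_profile_is_no_movement(self):
        with pytest.raises(NoMovementError):
            detect_peaks(_profile(np.zeros(500)), 3)

    def test_subthreshold_noise_bumps_ignored(self):
        prof = _pulse_train([1.5, 3.5, 5.5], [0.8, 1.1, 0.9])
        # five small bumps below the 0.1 m/s floor
        rng = np.random.default_rng(2)
        for c in rng.uniform(6.8, 7.8, 5):
            i = int(c * prof.rate)
            prof.v[i] = 0.08
        res = detect_peaks(prof, 3)
        assert res.matched and len(res.indices) == 3

    def test_threshold_iteration_separates_tall_peaks(self):
        # 4 peaks present but only 3 expected: the iterated threshold must
        # rise until the smallest peak drops out
        prof = _pulse_train([1.5, 3.0, 4.5, 6.0], [0.9, 1.1, 0.85, 0.3])
        res = detect_peaks(prof, 3)
        assert res.matched
        assert len(res.indices) == 3
        assert res.threshold > 0.3

    def test_stationary_padding_invariance(self):
        prof = _pulse_train([1.5, 3.5, 5.5], [0.8, 1.1, 0.9])
        padded = _profile(np.concatenate([np.zeros(200), prof.v,
                                          np.zeros(200)]))
        a = detect_peaks(prof, 3)
        b = detect_peaks(padded, 3)
        assert (b.indices - 200).tolist() == a.indices.tolist()

    def test_joint_fallback_uses_common_count(self):
        # IMU shows 4 peaks, reference 3: fall back to the largest
        # threshold where counts agree
        imu = _pulse_train([1.5, 3.0, 4.5, 6.0], [0.9, 1.1, 0.85, 0.3])
        ref = _pulse_train([1.5, 3.0, 4.5], [0.9, 1.1, 0.85], rate=200.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi, pr = detect_peaks_paired(imu, ref, 4)
        assert len(pi.indices) == len(pr.indices)


class TestOnsetOffset:
    def test_step_profile_onset_at_step(self):
        v = np.zeros(500)
        v[200:] = 1.0
        prof = _profile(v, source="reference")
        peak = 300
        assert find_onset(prof, peak) == 200

    def test_noisy_lead_in_defers_onset(self):
        # lead-in hum oscillating through the threshold and averaging 0.06
        # (above the 0.05 m/s quiet level): onset must not sit in the hum
        v = np.zeros(600)
        v[100:300:2] = 0.11
        v[100:300][1::2] = 0.01
        v[300:] = 1.0
        prof = _profile(v, source="reference")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            onset = find_onset(prof, 400)
        assert onset >= 300

    def test_step_down_offset_at_drop(self):
        v = np.ones(1000)
        v[900:] = 0.0
        prof = _profile(v, source="imu")
        assert find_offset(prof, 500) == 900

    def test_trailing_vibration_defers_offset(self):
        v = np.concatenate([np.ones(500), np.full(100, 0.07), np.zeros(300)])
        prof = _profile(v, source="imu")
        offset = find_offset(prof, 300)
        assert offset >= 600

    def test_simulator_events_within_30ms(self, block_pair):
        imu, _, gt = block_pair
        m = rk.process_imu_trial(imu)
        res = rk.imu_velocity(imu)
        onset_t = res.profile.t[m.onset_idx]
        offset_t = res.profile.t[m.offset_idx]
        # threshold events sit just inside the true movement window
        assert gt.onset_s - 0.03 <= onset_t <= gt.onset_s + 0.15
        assert gt.offset_s - 0.15 <= offset_t <= gt.offset_s + 0.03


class TestScalarMetrics:
    def test_movement_time_formula(self):
        assert movement_time(200, 900, 100.0) == pytest.approx(7000.0)
        assert movement_time(0, 0, 100.0) == 0.0

    def test_peak_velocity_closed_form(self):
        t = np.arange(101) / 100.0
        v = np.abs(minimum_jerk_velocity(0.25, 1.0, t))
        assert peak_velocity(v, 0, 100) == pytest.approx(0.46875, abs=1e-4)

    def test_peak_velocity_monotone_profile_is_endpoint(self):
        v = np.linspace(0, 1, 50)
        assert peak_velocity(v, 0, 49) == 1.0

    def test_peak_velocity_empty_window_rejected(self):
        with pytest.raises(UndefinedMetricError):
            peak_velocity(np.ones(10), 5, 4)


def sparc_dense_oracle(v, rate, params=None):
    """Arc-length integral on a 10x denser zero-padded grid (trapezoid)."""
    params = params or SparcParams()
    nfft = 1 << int(np.ceil(np.log2(max(10 * params.pad_factor * len(v),
                                        2))))
    mag = np.abs(np.fft.rfft(v, nfft))
    freq = np.fft.rfftfreq(nfft, d=1.0 / rate)
    mag = mag / mag[0]
    band = freq <= params.freq_cutoff
    f, m = freq[band], mag[band]
    th = params.amplitude_threshold
    i = np.flatnonzero(m >= th)[-1]
    frac = (m[i] - th) / (m[i] - m[i + 1])
    wc = f[i] + frac * (f[i + 1] - f[i])
    f = np.append(f[:i + 1], wc)
    m = np.append(m[:i + 1], th)
    dmdf = np.gradient(m, f)
    integrand = np.sqrt((1.0 / wc) ** 2 + dmdf**2)
    return -float(np.trapezoid(integrand, f))


class TestSparc:
    def _single_pulse(self):
        t = np.arange(101) / 100.0
        return np.abs(minimum_jerk_velocity(0.25, 1.0, t))

    def test_amplitude_scaling_invariance(self):
        v = self._single_pulse()
        assert sparc(2 * v, 100.0) == pytest.approx(sparc(v, 100.0),
                                                    abs=1e-12)

    def test_matches_dense_grid_oracle(self):
        v = self._single_pulse()
        assert sparc(v, 100.0) == pytest.approx(
            sparc_dense_oracle(v, 100.0), abs=1e-3)

    def test_two_submovements_less_smooth_than_one(self):
        t = np.arange(101) / 100.0
        pulse = np.abs(minimum_jerk_velocity(0.25, 1.0, t))
        gap = np.zeros(30)  # 0.3 s apart
        double = np.concatenate([pulse, gap, pulse])
        assert sparc(double, 100.0) < sparc(pulse, 100.0)

    def test_time_shift_invariance(self):
        v = self._single_pulse()
        shifted = np.concatenate([np.zeros(40), v, np.zeros(17)])
        # zero-padding shifts only change the spectrum phase, not |V|;
        # the different length changes the fft grid, so allow a small slack
        assert sparc(shifted, 100.0) == pytest.approx(sparc(v, 100.0),
                                                      abs=5e-3)

    def test_all_zero_profile_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sparc(np.zeros(100), 100.0)

    def test_nonconstant_profile_strictly_negative(self, block_pair):
        imu, _, _ = block_pair
        m = rk.process_imu_trial(imu)
        assert m.sparc < 0
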