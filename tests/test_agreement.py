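"""Concurrent-validity statistics: r, ICC(2,1), Bland-Altman."""

import numpy as np
import pytest

from reachkin.agreement import (bland_altman, build_report, icc_2_1,
                                pair_metric_tables, pearson_r,
                                systematic_error_check)
from reachkin.errors import UndefinedMetricError


class TestPearson:
    def test_identical_columns(self):
        a = np.array([1.0, 2, 3, 4, 5])
        assert pearson_r(a, a) == pytest.approx(1.0)

    def test_negated_columns(self):
        a = np.array([1.0, 2, 3, 4, 5])
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 6])
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (
            a.std() * b.std())
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 20))
        perm = rng.permutation(20)
        assert pearson_r(a[perm], b[perm]) == pytest.approx(pearson_r(a, b))


def icc_2_1_anova_oracle(a, b):
    """Independent sums-of-squares evaluation of ICC(2,1)."""
    Y = np.column_stack([a, b])
    n, k = Y.shape
    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    ss_rows = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_identical_columns_is_one(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        icc, lo, hi = icc_2_1(a, a)
        assert icc == pytest.approx(1.0)

    def test_matches_anova_oracle_on_fixture(self):
        a = np.array([9.0, 10.5, 12.0, 8.0, 14.5, 11.0])
        b = np.array([10.0, 11.0, 13.0, 8.5, 15.0, 11.5])
        icc, _, _ = icc_2_1(a, b)
        assert icc == pytest.approx(icc_2_1_anova_oracle(a, b), abs=1e-9)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        a = rng.normal(10, 3, 15)
        b = a + 0.5 + rng.normal(0, 1, 15)
        icc, lo, hi = icc_2_1(a, b)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(15), 2),
            "raters": np.repeat(["A", "B"], 15),
            "score": np.concatenate([a, b])})
        row = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        row = row[row.Type == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row.CI95), abs=0.01)

    def test_absolute_agreement_penalizes_constant_offset(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 10, 30)
        b = a + 5.0
        icc, _, _ = icc_2_1(a, b)
        # consistency ICC ignores the offset entirely
        Y = np.column_stack([a, b])
        n, k = Y.shape
        grand = Y.mean()
        msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((Y - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc) / (
            (n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert icc < 1.0
        assert icc < icc_consistency

    def test_equals_pearson_in_zero_rater_effect_limit(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 5, 30000)
        b = a + rng.normal(0, 1.0, 30000)
        A = np.concatenate([a, b])  # symmetrized: zero rater effect,
        B = np.concatenate([b, a])  # identical marginals
        icc, _, _ = icc_2_1(A, B)
        assert icc == pytest.approx(pearson_r(A, B), abs=1e-6)

    def test_degenerate_anova_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc_2_1(np.full(6, 2.0), np.full(6, 2.0))

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 2, 12)
        b = a + rng.normal(0, 1, 12)
        perm = rng.permutation(12)
        assert icc_2_1(a[perm], b[perm])[0] == pytest.approx(
            icc_2_1(a, b)[0], abs=1e-12)


class TestBlandAltman:
    def test_identical_columns(self):
        a = np.array([1.0, 2, 3, 4])
        ba = bland_altman(a, a)
        assert (ba.bias, ba.loa_low, ba.loa_high, ba.cv_percent) == (
            0.0, 0.0, 0.0, 0.0)

    def test_constant_offset_zero_sd(self):
        a = np.array([1.0, 2, 3, 4])
        ba = bland_altman(a, a + 5.0)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == pytest.approx(5.0)
        assert ba.loa_high == pytest.approx(5.0)

    def test_loa_half_width_is_1_96_sigma(self):
        rng = np.random.default_rng(7)
        a = rng.normal(100, 5, 10_000)
        b = a + rng.normal(0, 10, 10_000)
        ba = bland_altman(a, b)
        half = (ba.loa_high - ba.loa_low) / 2
        assert 19.2 <= half <= 20.0

    def test_loa_contain_at_least_93_percent(self):
        rng = np.random.default_rng(8)
        a = rng.normal(50, 3, 5000)
        b = a + rng.normal(1, 4, 5000)
        ba = bland_altman(a, b)
        inside = (ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high)
        assert inside.mean() >= 0.93

    def test_difference_direction_is_second_minus_first(self):
        ba = bland_altman(np.array([1.0, 1, 1]), np.array([2.0, 2, 2]))
        assert ba.bias == pytest.approx(1.0)


class TestSystematicError:
    def test_unbiased_data_passes(self):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 200)
        b = a + rng.normal(0, 1, 200)
        ok, slope = systematic_error_check(a, b)
        assert ok

    def test_large_offset_tiny_sd_fails(self):
        rng = np.random.default_rng(10)
        a = rng.normal(10, 2, 30)
        b = a + 5.0 + rng.normal(0, 0.01, 30)
        ok, _ = systematic_error_check(a, b)
        assert not ok

    def test_proportional_bias_slope_reported(self):
        rng = np.random.default_rng(11)
        a = rng.normal(10, 3, 500)
        b = a * 1.2  # difference grows with the mean
        _, slope = systematic_error_check(a, b)
        assert slope > 0.1


class TestReportAssembly:
    def _tables(self):
        import pandas as pd

        rng = np.random.default_rng(12)
        rows_i, rows_r = [], []
        for task in ("block", "drink"):
            for i in range(8):
                mt = rng.normal(3000, 300)
                pv = rng.normal(1.0, 0.1)
                sp = rng.normal(-2.5, 0.2)
                base = dict(trial_id=f"{task}_{i}", task=task)
                rows_r.append(dict(base, movement_time_ms=mt,
                                   peak_velocity_ms=pv, sparc=sp))
                rows_i.append(dict(base,
                                   movement_time_ms=mt + rng.normal(0, 20),
                                   peak_velocity_ms=pv + rng.normal(0, .01),
                                   sparc=sp + rng.normal(0, 0.02)))
        return pd.DataFrame(rows_i), pd.DataFrame(rows_r)

    def test_report_has_row_per_task_and_metric(self):
        imu, ref = self._tables()
        report = build_report(imu, ref)
        assert len(report.to_frame()) == 6  # 2 tasks x 3 metrics
        row = report.row("block", "movement_time")
        assert -1 <= row.r <= 1
        assert row.loa_low <= row.bias <= row.loa_high

    def test_identical_tables_give_perfect_agreement(self):
        imu, ref = self._tables()
        report = build_report(imu.copy(), imu.copy())
        frame = report.to_frame()
        assert np.allclose(frame.r, 1.0)
        assert np.allclose(frame.bias, 0.0)
        assert np.allclose(frame.icc, 1.0)

    def test_unmatched_trial_ids_rejected(self):
        imu, ref = self._tables()
        ref = ref[ref.trial_id != "block_3"]
        with pytest.raises(ValueError, match="block_3"):
            pair_metric_tables(imu, ref)

    def test_peak_velocity_reported_in_mm_per_s(self):
        imu, ref = self._tables()
        report = build_report(imu, ref)
        row = report.row("block", "peak_velocity")
        assert row.unit == "mm/s"
        assert row.mean_imu > 500  # ~1 m/s expressed in mm/s


def test_bland_altman_plot_writes_file(tmp_path):
    from reachkin.agreement import PairedMetricSet, bland_altman_plot

    rng = np.random.default_rng(0)
    a = rng.normal(3000, 200, 20)
    pairs = PairedMetricSet(metric="movement_time", task="block",
                            ref=a, imu=a + rng.normal(0, 30, 20))
    out = tmp_path / "ba.png"
    bland_altman_plot(pairs, out)
    assert out.stat().st_size > 0
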