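"""Concurrent-validity statistics for paired per-trial metrics.

Given matched per-trial metric values from the IMU pipeline and the optical
reference, computes Pearson r, ICC(2,1) (two-way random effects, absolute
agreement, single measures, with an F-based 95% CI), Bland-Altman bias and
limits of agreement, a method-comparison CV%, and a systematic-error check
on the mean difference. Differences are oriented IMU - reference
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError

#: Metrics reported, with their report units. Peak velocity is computed in
#: m/s internally but reported in mm/s (the conventional reporting unit for
#: wrist speeds in this literature).
METRIC_COLUMNS = {
    "movement_time_ms": ("movement_time", "ms", 1.0),
    "peak_velocity_ms": ("peak_velocity", "mm/s", 1000.0),
    "sparc": ("sparc", "-", 1.0),
}


@dataclass
class PairedMetricSet:
    """Per-trial (reference, imu) value pairs for one metric and task."""

    metric: str
    task: str
    ref: np.ndarray
    imu: np.ndarray

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.float64)
        self.imu = np.asarray(self.imu, dtype=np.float64)
        if self.ref.shape != self.imu.shape or self.ref.ndim != 1:
            raise ValueError("ref and imu must be 1-D arrays of equal length")
        if np.isnan(self.ref).any() or np.isnan(self.imu).any():
            raise ValueError("paired metric sets may not contain missing "
                             "values")

    @property
    def n(self) -> int:
        return len(self.ref)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 3:
        raise UndefinedMetricError("need n >= 3 pairs for Pearson r")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedMetricError("Pearson r undefined for zero variance")
    return float(stats.pearsonr(a, b).statistic)


def icc_2_1(a: np.ndarray, b: np.ndarray, ci: float = 0.95
            ) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA decomposition with n targets (trials) and k = 2
    raters (systems):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    with the F-based confidence interval of McGraw & Wong. Returns
    (icc, ci_low, ci_high).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = len(a)
    if n < 5:
        raise UndefinedMetricError("need n >= 5 pairs for the ICC CI")
    Y = np.column_stack([a, b])
    k = 2
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((Y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if msr == 0 or denom == 0:
        raise UndefinedMetricError("degenerate ANOVA: no between-trial "
                                   "variance")
    icc = (msr - mse) / denom

    alpha = 1.0 - ci
    a_coef = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a_coef):
        return float(icc), float(icc), float(icc)
    b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc))
    num_df = (a_coef * msc + b_coef * mse) ** 2
    den_df = ((a_coef * msc) ** 2 / (k - 1)
              + (b_coef * mse) ** 2 / ((n - 1) * (k - 1)))
    v = num_df / den_df if den_df > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return float(icc), float(lower), float(upper)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    cv_percent: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement of b against a (differences d = b - a).

    bias = mean(d); limits of agreement = bias +/- 1.96 SD(d); CV% =
    100 SD(d) / |grand mean of the pair averages| (a method-comparison CV).
    Also carries the (mean, difference) points for plotting.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2:
        raise UndefinedMetricError("need n >= 2 pairs for Bland-Altman")
    d = b - a
    m = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(m.mean())
    cv = 100.0 * sd / abs(grand) if grand != 0 else float("nan")
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, cv_percent=cv,
                       means=m, diffs=d)


def systematic_error_check(a: np.ndarray, b: np.ndarray
                           ) -> tuple[bool, float]:
    """Is zero inside the 95% CI of the mean difference?

    Returns (no_systematic_error, proportional_bias_slope). The CI is
    bias +/- t_{n-1, 0.975} SD(d)/sqrt(n) (the exact small-sample 95% CI;
    the t quantile tends to 1.96 for large n). The slope of d on the pair
    means is reported for proportional-bias inspection.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = len(a)
    if n < 5:
        raise UndefinedMetricError("need n >= 5 pairs")
    d = b - a
    m = (a + b) / 2.0
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ok = bool(abs(d.mean()) <= tcrit * se)
    if np.std(m) == 0:
        slope = 0.0
    else:
        slope = float(stats.linregress(m, d).slope)
    return ok, slope


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-task, per-metric agreement table (Pearson r, ICC, Bland-Altman)."""

    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def row(self, task: str, metric: str) -> pd.Series:
        sel = self.frame[(self.frame.task == task)
                         & (self.frame.metric == metric)]
        if sel.empty:
            raise KeyError((task, metric))
        return sel.iloc[0]


def pair_metric_tables(imu: pd.DataFrame, ref: pd.DataFrame
                       ) -> list[PairedMetricSet]:
    """Match the two per-trial metric tables on trial_id, per task/metric."""
    for name, df in (("imu", imu), ("reference", ref)):
        missing_cols = {"trial_id", "task"} - set(df.columns)
        if missing_cols:
            raise ValueError(f"{name} table lacks columns {missing_cols}")
    only_imu = set(imu.trial_id) - set(ref.trial_id)
    only_ref = set(ref.trial_id) - set(imu.trial_id)
    if only_imu or only_ref:
        raise ValueError(
            "unmatched trial ids: "
            f"imu-only={sorted(only_imu)[:10]}, "
            f"reference-only={sorted(only_ref)[:10]}")
    merged = imu.merge(ref, on=["trial_id", "task"],
                       suffixes=("_imu", "_ref"))
    if len(merged) != len(imu):
        raise ValueError("trial_id/task pairs do not match one-to-one")
    out = []
    for task in sorted(merged.task.unique()):
        sub = merged[merged.task == task]
        for metric in METRIC_COLUMNS:
            out.append(PairedMetricSet(
                metric=metric, task=task,
                ref=sub[f"{metric}_ref"].to_numpy(),
                imu=sub[f"{metric}_imu"].to_numpy()))
    return out


def build_report(imu: pd.DataFrame, ref: pd.DataFrame) -> AgreementReport:
    """Full agreement report across matched metric tables."""
    rows = []
    for pairs in pair_metric_tables(imu, ref):
        name, unit, scale = METRIC_COLUMNS[pairs.metric]
        a = pairs.ref * scale
        b = pairs.imu * scale
        r = pearson_r(a, b)
        icc, lo, hi = icc_2_1(a, b)
        ba = bland_altman(a, b)
        ok, slope = systematic_error_check(a, b)
        rows.append({
            "task": pairs.task, "metric": name, "unit": unit, "n": pairs.n,
            "mean_ref": a.mean(), "mean_imu": b.mean(),
            "r": r, "icc": icc, "icc_ci_low": lo, "icc_ci_high": hi,
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "cv_percent": ba.cv_percent,
            "no_systematic_error": ok, "prop_bias_slope": slope,
        })
    return AgreementReport(frame=pd.DataFrame(rows))


def bland_altman_plot(pairs: PairedMetricSet, path) -> None:
    """Write a Bland-Altman plot for one paired metric set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs.ref, pairs.imu)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of systems ({pairs.metric})")
    ax.set_ylabel("IMU - reference")
    ax.set_title(f"{pairs.task}: {pairs.metric}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
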