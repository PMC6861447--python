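"""Trial, report and ground-truth file I/O.

Trial dialect: comma-delimited data preceded by ``#``-prefixed ``key: value``
header lines (format, trial_id, task, rate_hz, units). IMU files carry
columns ``t,ax,ay,az,gx,gy,gz`` (s, g, deg/s); marker files carry
``t,x,y,z`` (s, mm) with *empty* fields for missing samples. Values are
written with 17 significant digits so write-read round-trips are exact for
finite float64 data.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import FormatError, UnprocessableTrialError
from .segmentation import _runs
from .types import GroundTruth, ImuTrial, MarkerTrial

_IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MARKER_COLUMNS = ["t", "x", "y", "z"]
_FMT = "%.17g"

#: Marker gaps of this many frames or more make a trial unprocessable.
MAX_GAP_FRAMES = 10


def _write_header(fh, kind: str, trial) -> None:
    fh.write(f"# format: reachkin-{kind} v1\n")
    fh.write(f"# trial_id: {trial.trial_id}\n")
    fh.write(f"# task: {trial.task}\n")
    fh.write(f"# rate_hz: {trial.rate:.17g}\n")
    units = ("t=s,a=g,g=deg/s" if kind == "imu" else "t=s,pos=mm")
    fh.write(f"# units: {units}\n")


def _read_header_and_body(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    header: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if ":" not in line:
                    raise FormatError(f"{path}:{lineno}: malformed header line")
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                body_lines.append((lineno, line))
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    first_lineno = body_lines[0][0]
    try:
        df = pd.read_csv(io.StringIO("".join(line for _, line in body_lines)),
                         skip_blank_lines=False,
                         float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: cannot parse data section: {exc}") from exc
    df.attrs["first_data_lineno"] = first_lineno
    for key in ("rate_hz", "task", "trial_id"):
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    return header, df


def write_imu_trial(trial: ImuTrial, path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "imu", trial)
        fh.write(",".join(_IMU_COLUMNS) + "\n")
        data = np.column_stack([trial.t, trial.acc, trial.gyr])
        np.savetxt(fh, data, fmt=_FMT, delimiter=",")


def read_imu_trial(path, validate: bool = True) -> ImuTrial:
    header, df = _read_header_and_body(path)
    missing = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df[_IMU_COLUMNS].isna().any().any():
        rows = np.flatnonzero(df[_IMU_COLUMNS].isna().any(axis=1))
        base = df.attrs["first_data_lineno"] + 1  # + column header line
        raise FormatError(
            f"{path}: malformed/empty fields at line(s) "
            f"{[int(base + r) for r in rows[:10]]}")
    trial = ImuTrial(
        t=df["t"].to_numpy(),
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyr=df[["gx", "gy", "gz"]].to_numpy(),
        rate=float(header["rate_hz"]),
        task=header["task"],
        trial_id=header["trial_id"],
    )
    if validate:
        trial.validate()
    return trial


def write_marker_trial(trial: MarkerTrial, path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "markers", trial)
        fh.write(",".join(_MARKER_COLUMNS) + "\n")
        for ti, p in zip(trial.t, trial.pos):
            cells = [_FMT % ti] + ["" if np.isnan(c) else _FMT % c for c in p]
            fh.write(",".join(cells) + "\n")


def read_marker_trial(path, validate: bool = True) -> MarkerTrial:
    header, df = _read_header_and_body(path)
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["t"].isna().any():
        raise FormatError(f"{path}: timestamps may not be missing")
    trial = MarkerTrial(
        t=df["t"].to_numpy(),
        pos=df[["x", "y", "z"]].to_numpy(),
        rate=float(header["rate_hz"]),
        task=header["task"],
        trial_id=header["trial_id"],
    )
    if validate:
        trial.validate()
    return trial


def fill_gaps(trial: MarkerTrial) -> MarkerTrial:
    """Cubic-spline interpolation of short marker occlusions.

    Gaps of 1-9 frames are filled per axis by a (not-a-knot) cubic spline
    through the observed samples; a gap of >= 10 frames, or a gap touching
    either end of the recording, makes the trial unprocessable. Observed
    samples are never altered.
    """
    missing = trial.missing
    if not missing.any():
        return trial
    gaps = _runs(missing)
    for start, stop in gaps:
        if stop - start >= MAX_GAP_FRAMES:
            raise UnprocessableTrialError(
                f"trial {trial.trial_id!r}: marker gap of {stop - start} "
                f"frames at sample {start} (only gaps of "
                f"<{MAX_GAP_FRAMES} frames are interpolable)")
        if start == 0 or stop == len(trial):
            raise UnprocessableTrialError(
                f"trial {trial.trial_id!r}: marker gap at the recording "
                "boundary cannot be interpolated")
    good = ~missing
    pos = trial.pos.copy()
    for axis in range(3):
        spline = CubicSpline(trial.t[good], trial.pos[good, axis])
        pos[missing, axis] = spline(trial.t[missing])
    return MarkerTrial(t=trial.t.copy(), pos=pos, rate=trial.rate,
                       task=trial.task, trial_id=trial.trial_id)


# ---------------------------------------------------------------------------
# reports and ground truth
# ---------------------------------------------------------------------------

def write_report(report, path, fmt: str | None = None) -> None:
    """Write an agreement report as CSV or JSON (by extension or `fmt`)."""
    df = report.to_frame()
    if df.empty:
        raise ValueError("refusing to write an empty agreement report: "
                         "no paired trials were available")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.10g")
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.as_dict(), indent=2))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
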