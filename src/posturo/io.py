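"""Readers and writers for the package's plain-text file formats.

Formats (all UTF-8, dot decimal):

* COP trial: CSV with a leading ``#``-comment metadata block and columns
  ``time_s,cop_x_mm,cop_y_mm``.
* Respiration trace: CSV with metadata block and columns
  ``time_s,resp_v``.
* Cohort table: TSV, long format, one row per
  (subject, inhalation_type, inhalation_time, outcome, value).
* Results: TSV, one row per ANOVA effect, pairwise comparison or
  correlation.

Readers validate and reject; they never silently coerce malformed input.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CopTrial, DataError, FormatError, RespSignal

_TIME_TOL = 1e-6  # s, allowed deviation from uniform spacing

COP_COLUMNS = ("time_s", "cop_x_mm", "cop_y_mm")
RESP_COLUMNS = ("time_s", "resp_v")
COHORT_COLUMNS = ("subject", "inhalation_type", "inhalation_time", "outcome", "value")
RESULT_COLUMNS = ("outcome", "effect", "df1", "df2", "F_or_r", "p", "eta_p2_or_band", "epsilon_GG")


def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    """Parse the leading ``# key: value`` comment block; return it and its size."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" not in body:
                raise FormatError(f"{path}: malformed metadata line {n}: {line!r}")
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta, n


def _check_uniform_time(time_s: np.ndarray, rate: float, path: Path) -> None:
    dt = 1.0 / rate
    expected = time_s[0] + dt * np.arange(len(time_s))
    bad = np.nonzero(np.abs(time_s - expected) > _TIME_TOL)[0]
    if bad.size:
        row = int(bad[0])
        raise FormatError(
            f"{path}: time column not uniform at declared {rate} Hz; "
            f"first bad row {row} (t={time_s[row]:.6f}, expected {expected[row]:.6f})"
        )


def write_cop_trial(trial: CopTrial, path: str | Path) -> Path:
    """Write a COP trial to CSV with full float precision."""
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.sampling_rate
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# subject: {trial.subject}\n")
        fh.write(f"# inhalation_type: {trial.inhalation_type}\n")
        fh.write(f"# timepoint: {trial.timepoint}\n")
        fh.write(f"# rep: {trial.rep}\n")
        fh.write(f"# sampling_rate_hz: {float(trial.sampling_rate)!r}\n")
        fh.write(",".join(COP_COLUMNS) + "\n")
        for ti, xi, yi in zip(t, trial.x, trial.y):
            fh.write(f"{float(ti)!r},{float(xi)!r},{float(yi)!r}\n")
    return path


def read_cop_trial(path: str | Path) -> CopTrial:
    """Read and validate one COP trial file.

    Raises :class:`FormatError` on missing columns/metadata or a
    non-uniform time column, :class:`DataError` on non-finite values.
    """
    path = Path(path)
    meta, n_meta = _read_metadata(path)
    required = ("subject", "inhalation_type", "timepoint", "rep", "sampling_rate_hz")
    missing = [k for k in required if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    frame = pd.read_csv(path, skiprows=n_meta, float_precision="round_trip")
    if tuple(frame.columns) != COP_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {COP_COLUMNS}, found {tuple(frame.columns)}"
        )
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError(f"{path}: non-finite value in data block")
    rate = float(meta["sampling_rate_hz"])
    if rate <= 0:
        raise FormatError(f"{path}: sampling_rate_hz must be positive")
    _check_uniform_time(values[:, 0], rate, path)
    return CopTrial(
        subject=meta["subject"],
        inhalation_type=meta["inhalation_type"],
        timepoint=meta["timepoint"],
        rep=int(meta["rep"]),
        sampling_rate=rate,
        x=values[:, 1],
        y=values[:, 2],
    )


def write_resp_signal(signal: RespSignal, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(signal.samples)) / signal.sampling_rate
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# condition: {signal.condition}\n")
        fh.write(f"# phase: {signal.phase}\n")
        fh.write(f"# sampling_rate_hz: {float(signal.sampling_rate)!r}\n")
        windows = ";".join(f"{float(a)!r}-{float(b)!r}" for a, b in signal.window_bounds)
        fh.write(f"# windows: {windows}\n")
        fh.write(",".join(RESP_COLUMNS) + "\n")
        for ti, vi in zip(t, signal.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")
    return path


def read_resp_signal(path: str | Path) -> RespSignal:
    path = Path(path)
    meta, n_meta = _read_metadata(path)
    if "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: missing metadata key 'sampling_rate_hz'")
    frame = pd.read_csv(path, skiprows=n_meta, float_precision="round_trip")
    if tuple(frame.columns) != RESP_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {RESP_COLUMNS}, found {tuple(frame.columns)}"
        )
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError(f"{path}: non-finite value in data block")
    rate = float(meta["sampling_rate_hz"])
    _check_uniform_time(values[:, 0], rate, path)
    windows = []
    for part in filter(None, meta.get("windows", "").split(";")):
        a, _, b = part.partition("-")
        windows.append((float(a), float(b)))
    return RespSignal(
        samples=values[:, 1],
        sampling_rate=rate,
        condition=meta.get("condition", ""),
        phase=meta.get("phase", ""),
        window_bounds=tuple(windows),
    )


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format cohort outcome table as TSV."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    table = table.loc[:, list(COHORT_COLUMNS)].sort_values(
        list(COHORT_COLUMNS[:4]), kind="mergesort"
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    if frame["value"].isna().any():
        raise DataError(f"{path}: missing value in cohort table")
    return frame


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_results_table(rows: Iterable[dict], path: str | Path) -> Path:
    """Write ANOVA / pairwise / correlation results to a deterministic TSV.

    Each row is a dict with a subset of :data:`RESULT_COLUMNS`; absent
    fields are written as ``NA``.  Refuses an empty result set.
    """
    rows = list(rows)
    if not rows:
        raise DataError("refusing to write an empty results table")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            unknown = set(row) - set(RESULT_COLUMNS)
            if unknown:
                raise FormatError(f"unknown result columns {sorted(unknown)}")
            fh.write("\t".join(_fmt(row.get(c)) for c in RESULT_COLUMNS) + "\n")
    return Path(path)
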