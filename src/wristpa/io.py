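"""CSV readers and writers for the study's file dialects.

Raw acceleration: ``timestamp,x,y,z`` (ISO-8601 timestamps, axes in g).
Breaths: ``timestamp,vo2_ml_min`` (extra columns such as vco2 ignored).
Sleep/non-wear log: ``participant,date,sleep_start,sleep_end,
nonwear_start,nonwear_end`` with one interval per row; an end time at or
before its start means the interval crosses midnight into the next day.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import RawAccelStream, Segment
from .calorimetry import BreathStream


class CsvFormatError(ValueError):
    """A CSV row failed to parse; the message names file and line."""


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise CsvFormatError(
            f"{path}: line {line}: non-numeric value {df[col].iloc[line - 2]!r} "
            f"in column {col!r}"
        )
    if vals.isna().any():
        line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
        raise CsvFormatError(f"{path}: line {line}: missing value in column {col!r}")
    return vals.to_numpy(dtype=float)


def _timestamps(df: pd.DataFrame, path: Path) -> np.ndarray:
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2
        raise CsvFormatError(
            f"{path}: line {line}: unparseable timestamp "
            f"{df['timestamp'].iloc[line - 2]!r}"
        )
    return ts.to_numpy().astype("datetime64[ms]")


def read_accel_csv(
    path: str | Path, device_id: str, fs: float, dtype=np.float32
) -> RawAccelStream:
    """Read a raw acceleration CSV, splitting segments at sample gaps.

    A gap larger than 1.5 sample intervals starts a new segment, so
    dropout periods become absent samples rather than stretched ones.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"timestamp", "x", "y", "z"} - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing column(s) {sorted(missing)}")
    times = _timestamps(df, path)
    xyz = np.column_stack([_numeric(df, c, path) for c in ("x", "y", "z")]).astype(dtype)
    if len(times) == 0:
        raise CsvFormatError(f"{path}: no samples")
    dt = np.diff(times) / np.timedelta64(1, "ms")
    if (dt <= 0).any():
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise CsvFormatError(f"{path}: line {line}: timestamps not increasing")
    breaks = np.flatnonzero(dt > 1.5 * 1000.0 / fs) + 1
    segments = [
        Segment(start=times[i], data=xyz[i:j])
        for i, j in zip(np.r_[0, breaks], np.r_[breaks, len(times)])
    ]
    return RawAccelStream(device_id=device_id, fs=fs, segments=segments)


def read_breath_csv(path: str | Path, body_mass_kg: float) -> BreathStream:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"timestamp", "vo2_ml_min"} - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return BreathStream(
        times=_timestamps(df, path),
        vo2=_numeric(df, "vo2_ml_min", path),
        body_mass_kg=body_mass_kg,
    )


def _hhmm(date: np.datetime64, hhmm: str) -> pd.Timestamp:
    h, m = hhmm.split(":")
    return pd.Timestamp(date) + pd.Timedelta(hours=int(h), minutes=int(m))


def read_sleep_log(path: str | Path) -> dict[str, dict[str, list]]:
    """Parse the log into per-participant sleep and non-wear intervals.

    Returns ``{participant: {"sleep": [(start, end), ...],
    "nonwear": [...]}}`` with absolute timestamps; intervals whose end is
    not after their start roll over to the next day.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[str, dict[str, list]] = {}
    for i, row in df.iterrows():
        pid = row["participant"]
        rec = out.setdefault(pid, {"sleep": [], "nonwear": []})
        date = np.datetime64(row["date"])
        for kind in ("sleep", "nonwear"):
            s, e = row[f"{kind}_start"], row[f"{kind}_end"]
            if not s and not e:
                continue
            if not s or not e:
                raise CsvFormatError(
                    f"{path}: line {int(i) + 2}: {kind} interval needs both start and end"
                )
            start, end = _hhmm(date, s), _hhmm(date, e)
            if end <= start:
                end += pd.Timedelta(days=1)
            rec[kind].append((start, end))
    return out


def read_participants(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"participant", "body_mass_kg"} - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_epochs_csv(epochs: pd.DataFrame, path: str | Path) -> None:
    epochs.to_csv(path, index=True, float_format="%.4f")


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False, float_format="%.6f")
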