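"""Align epoch streams on the shared analysis set and summarise.

Sources are inner-joined on the 60-s epoch grid restricted to the
analysis set (worn, awake, valid minutes), so every retained minute is
observed by every requested source. Summaries report minutes per
intensity class per participant — averaged over included days for
free-living data (min/day) or totalled for a single protocol session.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .nonwear import analysis_set

log = logging.getLogger(__name__)

ACCEL_CLASS_COLS = {"SED": "sed_s", "LPA": "lpa_s", "MVPA": "mvpa_s"}
#: calorimetry MET classes folded into accelerometer-comparable classes
MET_TO_CLASS = {"SED": "SED", "LPA": "LPA", "MPA": "MVPA", "VPA": "MVPA"}


class NoValidOverlapError(ValueError):
    """No epoch is simultaneously valid in every requested source."""


def _is_accel(df: pd.DataFrame) -> bool:
    return "sed_s" in df.columns


def merge_streams(
    epochs_by_source: dict[str, pd.DataFrame],
    mask: pd.DataFrame,
) -> pd.DataFrame:
    """Inner join of epoch tables over the analysis set.

    ``epochs_by_source`` maps a source name (e.g. ``TEST``, ``CRITERION``,
    ``CALORIMETRY``) to its epoch DataFrame. A minute is kept iff it is
    in the analysis set and every source has a valid epoch there
    (accelerometer: ``valid`` flag; calorimetry: a classified MET).
    Returns a DataFrame with MultiIndex columns ``(source, field)``.
    Raises :class:`NoValidOverlapError` when the intersection is empty.
    """
    if not epochs_by_source:
        raise ValueError("no sources given")
    keep = analysis_set(mask)
    pieces = {}
    for name, df in sorted(epochs_by_source.items()):
        sub = df.reindex(keep)
        if _is_accel(sub):
            ok = sub["valid"].eq(True)
        else:
            ok = sub["met_class"].notna()
        pieces[name] = sub[ok.to_numpy()]
    common = None
    for sub in pieces.values():
        common = sub.index if common is None else common.intersection(sub.index)
    if common is None or len(common) == 0:
        raise NoValidOverlapError(
            "no valid overlap: the requested sources share no valid analysis epoch"
        )
    merged = pd.concat(
        {name: sub.reindex(common) for name, sub in pieces.items()}, axis=1
    )
    merged.index.name = "epoch_start"
    log.info(
        "merged %d sources on %d/%d analysis minutes",
        len(pieces), len(common), len(keep),
    )
    return merged


def _source_minutes(sub: pd.DataFrame) -> dict[str, float]:
    """Minutes per class for one source over a set of merged epochs."""
    out = {}
    if _is_accel(sub):
        for cls, col in ACCEL_CLASS_COLS.items():
            out[cls] = float(sub[col].sum()) / 60.0
    else:
        folded = sub["met_class"].map(MET_TO_CLASS)
        counts = folded.value_counts()
        for cls in ACCEL_CLASS_COLS:
            out[cls] = float(counts.get(cls, 0))
    out["TPA"] = out["LPA"] + out["MVPA"]
    out["WEAR"] = float(len(sub))
    return out


def summarize(
    merged: pd.DataFrame,
    period: str = "per-day",
    participant: str = "",
    min_valid_day_min: float = 0.0,
) -> pd.DataFrame:
    """Per-source activity summaries from a merged epoch table.

    ``period='per-session'`` totals minutes over the whole table;
    ``period='per-day'`` computes each calendar day's minutes and then
    averages over days with at least ``min_valid_day_min`` analysis
    minutes (default: any valid time), yielding min/day. Returns one row
    per source with columns ``participant, device, period, sed_min,
    lpa_min, mvpa_min, tpa_min, wear_min, n_days``.
    """
    if merged.empty:
        raise ValueError("merged table is empty")
    if period not in ("per-day", "per-session"):
        raise ValueError(f"unknown period {period!r}")
    sources = merged.columns.get_level_values(0).unique()
    rows = []
    for src in sources:
        sub = merged[src]
        if period == "per-session":
            mins = _source_minutes(sub)
            n_days = 1
        else:
            daily = []
            for _, day_df in sub.groupby(sub.index.normalize()):
                m = _source_minutes(day_df)
                if m["WEAR"] >= max(min_valid_day_min, 1e-12):
                    daily.append(m)
            if not daily:
                warnings.warn(
                    f"participant {participant!r}: no day meets the valid-day "
                    f"rule; source {src} excluded",
                    stacklevel=2,
                )
                continue
            mins = {k: float(np.mean([d[k] for d in daily])) for k in daily[0]}
            n_days = len(daily)
        rows.append(
            {
                "participant": participant,
                "device": src,
                "period": period,
                "sed_min": mins["SED"],
                "lpa_min": mins["LPA"],
                "mvpa_min": mins["MVPA"],
                "tpa_min": mins["TPA"],
                "wear_min": mins["WEAR"],
                "n_days": n_days,
            }
        )
    return pd.DataFrame(rows)
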