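"""Wear, sleep, and valid time on the 60-s epoch grid.

Wear detection follows the Choi rule for wrist-count data: a maximal run
of zero-count minutes (allowing short "artifactual" nonzero spikes that
are flanked by long zero stretches) of at least 90 minutes is non-wear.
Because the rest of this pipeline works in ENMO rather than proprietary
counts, a per-minute movement proxy (rounded mean ENMO with a stillness
floor) stands in for the zero-count series; sleep comes from the
self-report log, and dropout of the test device invalidates the minute
for both devices so that exclusion is never differential.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MINUTE = np.timedelta64(60, "s")


def _runs(is_zero: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of (start, length, zero?) covering the series."""
    out = []
    n = len(is_zero)
    i = 0
    while i < n:
        j = i
        while j < n and is_zero[j] == is_zero[i]:
            j += 1
        out.append((i, j - i, bool(is_zero[i])))
        i = j
    return out


def choi_nonwear(
    movement: np.ndarray,
    window_min: int = 90,
    spike_tol_min: int = 2,
    spike_win_min: int = 30,
) -> np.ndarray:
    """Per-minute wear flags from a non-negative movement-count series.

    A nonzero run of at most ``spike_tol_min`` minutes counts as
    artifactual iff it is flanked on both sides by at least
    ``spike_win_min`` consecutive zero minutes. Any maximal run of
    zero-or-artifactual minutes with total length >= ``window_min`` is
    non-wear; everything else is wear. Returns a boolean array where
    True means wear.
    """
    movement = np.asarray(movement, dtype=float)
    if movement.ndim != 1:
        raise ValueError("movement series must be one-dimensional")
    if (movement < 0).any():
        raise ValueError("movement counts must be non-negative")
    n = len(movement)
    if n == 0:
        return np.zeros(0, dtype=bool)
    is_zero = movement == 0
    runs = _runs(is_zero)
    # mark short nonzero runs flanked by long zero runs as artifactual
    zero_like = is_zero.copy()
    for k, (start, length, zero) in enumerate(runs):
        if zero or length > spike_tol_min:
            continue
        left_ok = k > 0 and runs[k - 1][2] and runs[k - 1][1] >= spike_win_min
        right_ok = (
            k + 1 < len(runs) and runs[k + 1][2] and runs[k + 1][1] >= spike_win_min
        )
        if left_ok and right_ok:
            zero_like[start : start + length] = True
    wear = np.ones(n, dtype=bool)
    for start, length, zero in _runs(zero_like):
        if zero and length >= window_min:
            wear[start : start + length] = False
    return wear


def movement_proxy(epochs: pd.DataFrame, floor_mg: float = 1.0) -> pd.Series:
    """Zero-count analogue from epoch mean ENMO.

    Per minute, movement = round(mean ENMO in mg); values below
    ``floor_mg`` (the stillness floor, i.e. the stationary noise level
    of the sensor) are set to zero so a device at rest produces a zero
    series exactly as count data would. Missing epochs map to zero.
    """
    v = epochs["mean_enmo_mg"].to_numpy(dtype=float)
    out = np.round(np.where(np.isnan(v), 0.0, v))
    out[np.nan_to_num(v) < floor_mg] = 0.0
    return pd.Series(out, index=epochs.index, name="movement")


def _minute_grid(*indexes: pd.DatetimeIndex) -> pd.DatetimeIndex:
    start = min(ix.min() for ix in indexes)
    end = max(ix.max() for ix in indexes)
    return pd.date_range(start, end, freq="60s", name="epoch_start")


def build_mask(
    epochs_test: pd.DataFrame,
    epochs_criterion: pd.DataFrame,
    sleep_intervals: list[tuple] | None = None,
    window_min: int = 90,
    spike_tol_min: int = 2,
    spike_win_min: int = 30,
    stillness_floor_mg: float = 1.0,
) -> pd.DataFrame:
    """Combine Choi wear, logged sleep, and dropout into one shared mask.

    Wear is detected on the criterion stream's movement proxy (one shared
    mask for both devices avoids differential exclusion). A minute is
    invalid when the test-device epoch is absent or not valid (Bluetooth
    dropout) or when the criterion epoch is absent/invalid. The analysis
    set is ``wear & ~sleep & ~invalid``.
    """
    grid = _minute_grid(epochs_test.index, epochs_criterion.index)
    crit = epochs_criterion.reindex(grid)
    test = epochs_test.reindex(grid)
    movement = movement_proxy(crit, floor_mg=stillness_floor_mg).to_numpy()
    movement = np.nan_to_num(movement)  # missing minutes treated as zero
    wear = choi_nonwear(movement, window_min, spike_tol_min, spike_win_min)

    sleep = np.zeros(len(grid), dtype=bool)
    for start, end in sleep_intervals or []:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start >= grid[-1] + MINUTE or end <= grid[0]:
            warnings.warn(
                f"sleep interval {start}..{end} outside recording span; clipped",
                stacklevel=2,
            )
            continue
        sleep |= (grid >= start) & (grid < end)

    invalid = (
        ~test["valid"].eq(True).to_numpy() | ~crit["valid"].eq(True).to_numpy()
    )
    mask = pd.DataFrame(
        {"wear": wear, "sleep": sleep, "invalid": invalid}, index=grid
    )
    analysis = mask["wear"] & ~mask["sleep"] & ~mask["invalid"]
    log.info(
        "mask: %d min span, %d non-wear, %d sleep, %d invalid, %d analysis",
        len(mask),
        int((~mask["wear"]).sum()),
        int(mask["sleep"].sum()),
        int(mask["invalid"].sum()),
        int(analysis.sum()),
    )
    return mask


def analysis_set(mask: pd.DataFrame) -> pd.DatetimeIndex:
    """Minutes that enter statistical analysis: wear, awake, valid."""
    keep = mask["wear"] & ~mask["sleep"] & ~mask["invalid"]
    return mask.index[keep]
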