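"""Breath-level oxygen uptake to 60-s MET epochs with intensity classes.

Breath-by-breath VO2 (mL·min⁻¹) is collapsed by sample-and-hold time
weighting onto 10-s bins (emulating a vendor epoch export), 10-s bins are
averaged into 60-s epochs, and epoch VO2 is converted to METs with the
conventional resting value 1 MET = 3.5 mL·kg⁻¹·min⁻¹. MET classes use
continuous half-open bands with breakpoints 1.5, 3.0, 6.0: values at or
below 1.5 are sedentary, above 1.5 and below 3.0 light, 3.0 up to (but
not including) 6.0 moderate, and 6.0 or more vigorous. The printed band
edges in the activity-intensity literature (1.6–2.9 etc.) leave rounding
gaps; the continuous bands close them so every MET value is classified.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MET_PER_KG = 3.5  # mL O2 per kg per minute at rest

#: MET class labels in increasing intensity order
MET_CLASSES = ("SED", "LPA", "MPA", "VPA")


@dataclass
class BreathStream:
    """Ordered breath records: times (datetime64[ms]) and VO2 in mL/min."""

    times: np.ndarray
    vo2: np.ndarray
    body_mass_kg: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ms]")
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if len(self.times) != len(self.vo2):
            raise ValueError("times and vo2 must have equal length")
        if len(self.times) > 1 and (np.diff(self.times) <= np.timedelta64(0, "ms")).any():
            raise ValueError("breath timestamps must be strictly increasing")
        if (self.vo2 < 0).any():
            raise ValueError("VO2 must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "vo2_ml_min": self.vo2})


def vo2_to_met(mean_vo2: float | np.ndarray, body_mass_kg: float) -> float | np.ndarray:
    """MET = VO2 [mL/min] / (3.5 * body mass [kg])."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return mean_vo2 / (MET_PER_KG * body_mass_kg)


def classify_met(
    met: float | np.ndarray, breakpoints: tuple[float, float, float] = (1.5, 3.0, 6.0)
):
    """MET intensity class: SED <= b0 < LPA < b1 <= MPA < b2 <= VPA.

    Monotone non-decreasing in MET and defined for every non-negative
    value (no gaps between bands).
    """
    b0, b1, b2 = breakpoints
    arr = np.asarray(met, dtype=float)
    if (arr < 0).any():
        raise ValueError("MET must be non-negative")
    codes = (arr > b0).astype(int) + (arr >= b1) + (arr >= b2)
    if arr.ndim == 0:
        return MET_CLASSES[int(codes)]
    return np.array(MET_CLASSES, dtype=object)[codes]


def _hold_functions(rel_s: np.ndarray, vo2: np.ndarray, max_hold_s: float):
    """Integral and coverage of the capped sample-and-hold step signal.

    Each breath's value holds from its timestamp until the next breath,
    but for at most ``max_hold_s`` seconds — longer silences are treated
    as uncovered (mask off, signal dropout) rather than bridged. Returns
    callables ``I(t)`` (integral of the held signal over covered time up
    to t) and ``C(t)`` (covered seconds up to t).
    """
    start = rel_s[:-1]
    end = np.minimum(rel_s[1:], rel_s[:-1] + max_hold_s)
    hold = end - start
    cum_i = np.concatenate([[0.0], np.cumsum(vo2[:-1] * hold)])
    cum_c = np.concatenate([[0.0], np.cumsum(hold)])

    def locate(t):
        t = np.clip(t, rel_s[0], rel_s[-1])
        k = np.searchsorted(start, t, side="right") - 1
        k = np.clip(k, 0, len(start) - 1)
        frac = np.clip(t - start[k], 0.0, hold[k])
        return k, frac

    def integral(t):
        k, frac = locate(t)
        return cum_i[k] + vo2[k] * frac

    def coverage(t):
        k, frac = locate(t)
        return cum_c[k] + frac

    return integral, coverage


def collapse_breaths(
    stream: BreathStream,
    intermediate_s: int = 10,
    final_s: int = 60,
    min_bins: int = 3,
    met_breakpoints: tuple[float, float, float] = (1.5, 3.0, 6.0),
    max_hold_s: float | None = None,
) -> pd.DataFrame:
    """Collapse breaths to MET-classified epochs.

    Each breath's VO2 value is held until the next breath (capped at
    ``max_hold_s``, default one bin width, so silent stretches count as
    uncovered); 10-s bins on wall-clock boundaries get the
    duration-weighted mean of the held signal over the covered part of
    the bin, and each 60-s epoch is the arithmetic mean of its available
    10-s bins. Epochs with fewer than ``min_bins`` of the
    ``final_s / intermediate_s`` bins present are missing (NaN VO2, no
    class).

    Returns a DataFrame indexed by ``epoch_start`` with columns
    ``mean_vo2, met, met_class``.
    """
    if final_s % intermediate_s:
        raise ValueError("final_s must be a multiple of intermediate_s")
    times, vo2 = stream.times, stream.vo2
    if len(times) == 0:
        return pd.DataFrame(
            columns=["mean_vo2", "met", "met_class"],
            index=pd.DatetimeIndex([], name="epoch_start"),
        )
    t0 = times[0].astype("datetime64[s]").astype("datetime64[ms]")
    # align the bin grid to wall-clock multiples of final_s
    day = t0.astype("datetime64[D]").astype("datetime64[ms]")
    off = float((t0 - day) / np.timedelta64(1000, "ms"))
    grid0 = day + np.timedelta64(int(off // final_s) * final_s * 1000, "ms")

    rel = (times - grid0) / np.timedelta64(1000, "ms")  # seconds from grid origin
    rel = rel.astype(float)
    span_end = rel[-1]
    n_bins = int(np.ceil(span_end / intermediate_s))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * float(intermediate_s)
    if max_hold_s is None:
        max_hold_s = float(intermediate_s)
    if len(times) < 2:
        bin_mean = np.full(n_bins, np.nan)
    else:
        integral, coverage = _hold_functions(rel, vo2, max_hold_s)
        covered = coverage(edges[1:]) - coverage(edges[:-1])
        bin_int = integral(edges[1:]) - integral(edges[:-1])
        bin_mean = np.full(n_bins, np.nan)
        has = covered > 0
        bin_mean[has] = bin_int[has] / covered[has]
    bins_per_epoch = final_s // intermediate_s
    n_epochs = int(np.ceil(n_bins / bins_per_epoch))
    pad = n_epochs * bins_per_epoch - n_bins
    padded = np.concatenate([bin_mean, np.full(pad, np.nan)]).reshape(
        n_epochs, bins_per_epoch
    )
    present = (~np.isnan(padded)).sum(axis=1)
    sums = np.nansum(padded, axis=1)
    mean_vo2 = np.full(n_epochs, np.nan)
    ok_ep = present >= max(min_bins, 1)
    mean_vo2[ok_ep] = sums[ok_ep] / present[ok_ep]
    met = np.where(
        np.isnan(mean_vo2), np.nan, vo2_to_met(np.nan_to_num(mean_vo2), stream.body_mass_kg)
    )
    met_class = np.full(n_epochs, None, dtype=object)
    ok = ~np.isnan(met)
    if ok.any():
        met_class[ok] = classify_met(met[ok], met_breakpoints)
    index = pd.DatetimeIndex(
        grid0 + (np.arange(n_epochs) * final_s * 1000).astype("timedelta64[ms]"),
        name="epoch_start",
    )
    return pd.DataFrame(
        {"mean_vo2": mean_vo2, "met": met, "met_class": met_class}, index=index
    )
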