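"""Raw tri-axial acceleration to per-second ENMO and 60-s epoch records.

The processing chain mirrors the standard raw-accelerometry reduction used
for wrist-worn devices: a static-window autocalibration brings the gravity
vector to unit norm, the Euclidean norm minus one (ENMO, negatives rounded
to zero) summarises movement per sample, per-second means are classified
against milli-g cut-points, and seconds are collapsed into wall-clock
aligned 60-s epochs carrying intensity-seconds tallies and validity flags.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import CutPoints

MS = np.timedelta64(1, "ms")
SECOND = np.timedelta64(1, "s")

#: integer class codes used throughout; -1 marks a missing second
SED, LPA, MVPA = 0, 1, 2
MISSING = -1
CLASS_NAMES = {SED: "SED", LPA: "LPA", MVPA: "MVPA"}


@dataclass
class Segment:
    """A contiguous, gap-free run of samples at the nominal rate."""

    start: np.datetime64  # datetime64[ms] of the first sample
    data: np.ndarray      # (n, 3) acceleration in g

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class RawAccelStream:
    """Timestamped tri-axial samples from one device.

    Samples are stored as contiguous segments; gaps (e.g. Bluetooth
    dropout) are simply the spans between segments. Sample ``k`` of a
    segment is located at ``start + k / fs`` seconds.
    """

    device_id: str
    fs: float
    segments: list[Segment]
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return sum(s.n for s in self.segments)

    @property
    def start(self) -> np.datetime64:
        return self.segments[0].start

    @property
    def end(self) -> np.datetime64:
        last = self.segments[-1]
        return last.start + np.timedelta64(round(last.n * 1000 / self.fs), "ms")

    def duration_s(self) -> float:
        return float((self.end - self.start) / SECOND)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a ``timestamp, x, y, z`` DataFrame (CSV dialect)."""
        frames = []
        for seg in self.segments:
            offs = (np.round(np.arange(seg.n) * 1000.0 / self.fs)).astype("timedelta64[ms]")
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": seg.start + offs,
                        "x": seg.data[:, 0],
                        "y": seg.data[:, 1],
                        "z": seg.data[:, 2],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class EnmoSeries:
    """Per-second ENMO (milli-g) on a contiguous wall-clock second grid.

    ``values`` is NaN where the second has insufficient coverage;
    ``coverage`` is the fraction of expected samples present.
    """

    start: np.datetime64  # datetime64[s]-aligned grid origin
    values: np.ndarray    # (n,) float, milli-g, NaN = missing
    coverage: np.ndarray  # (n,) float in [0, 1]

    @property
    def n(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n) * SECOND


def _second_offsets(seg: Segment, fs: float, t0: np.datetime64) -> np.ndarray:
    """Integer second index of each sample relative to grid origin t0."""
    base_s = float((seg.start - t0) / MS) / 1000.0
    return np.floor(base_s + np.arange(seg.n) / fs).astype(np.int64)


def compute_enmo(stream: RawAccelStream, min_coverage: float = 0.5) -> EnmoSeries:
    """Per-second mean ENMO in milli-g.

    Per sample, ENMO = max(sqrt(x^2 + y^2 + z^2) - 1, 0) in g, i.e. the
    Euclidean norm minus one with negative values rounded to zero; the
    per-second value is the arithmetic mean of the sample ENMOs falling
    in that wall-clock second. Seconds whose sample coverage is below
    ``min_coverage`` are marked missing (NaN).
    """
    if not stream.segments:
        raise ValueError("empty stream")
    t0 = stream.start.astype("datetime64[s]")
    n_seconds = int(np.ceil(float((stream.end - t0) / MS) / 1000.0))
    n_seconds = max(n_seconds, 1)
    sums = np.zeros(n_seconds)
    counts = np.zeros(n_seconds, dtype=np.int64)
    for seg in stream.segments:
        xyz = seg.data.astype(np.float64, copy=False)
        enmo = np.sqrt(np.einsum("ij,ij->i", xyz, xyz)) - 1.0
        np.maximum(enmo, 0.0, out=enmo)
        idx = _second_offsets(seg, stream.fs, t0)
        sums += np.bincount(idx, weights=enmo, minlength=n_seconds)
        counts += np.bincount(idx, minlength=n_seconds)
    coverage = counts / stream.fs
    np.clip(coverage, 0.0, 1.0, out=coverage)
    values = np.full(n_seconds, np.nan)
    ok = coverage >= min_coverage
    values[ok] = sums[ok] / counts[ok] * 1000.0  # g -> milli-g
    return EnmoSeries(start=t0, values=values, coverage=coverage)


def classify_seconds(enmo: EnmoSeries, cuts: CutPoints) -> np.ndarray:
    """Per-second intensity codes (SED/LPA/MVPA, MISSING where NaN).

    Boundary convention: a value exactly at a cut-point takes the higher
    class (>= threshold reading of the cut-point literature).
    """
    v = enmo.values
    classes = np.full(enmo.n, MISSING, dtype=np.int8)
    ok = ~np.isnan(v)
    vv = v[ok]
    classes[ok] = (vv >= cuts.sed_lpa).astype(np.int8) + (vv >= cuts.lpa_mvpa)
    return classes


def collapse_to_epochs(
    classes: np.ndarray,
    enmo: EnmoSeries,
    epoch_len_s: int = 60,
    missing_tol_s: int = 0,
) -> pd.DataFrame:
    """Collapse per-second classes into wall-clock aligned epoch records.

    Returns a DataFrame indexed by ``epoch_start`` with columns
    ``sed_s, lpa_s, mvpa_s, missing_s, mean_enmo_mg, valid``. Epochs are
    aligned to multiples of ``epoch_len_s`` from midnight (wall-clock
    minutes for the default), which is what makes cross-device merging
    on epoch timestamps possible. ``valid`` requires the number of
    missing seconds to be at most ``missing_tol_s``.
    """
    if epoch_len_s <= 0 or 3600 % epoch_len_s:
        raise ValueError("epoch_len_s must divide 3600")
    if len(classes) != enmo.n:
        raise ValueError("classes and enmo series length mismatch")
    step = np.timedelta64(epoch_len_s, "s")
    t0 = enmo.start
    # align the grid origin down to an epoch boundary
    day = t0.astype("datetime64[D]").astype("datetime64[s]")
    offset = int((t0 - day) / SECOND)
    lead = offset % epoch_len_s
    grid0 = t0 - np.timedelta64(lead, "s")
    n_epochs = int(np.ceil((lead + enmo.n) / epoch_len_s))
    sec_epoch = (lead + np.arange(enmo.n)) // epoch_len_s

    def tally(code: int) -> np.ndarray:
        return np.bincount(sec_epoch[classes == code], minlength=n_epochs)

    sed, lpa, mvpa = tally(SED), tally(LPA), tally(MVPA)
    # missing includes seconds outside the recording span of edge epochs
    missing = epoch_len_s - sed - lpa - mvpa
    present = ~np.isnan(enmo.values)
    n_present = np.bincount(sec_epoch[present], minlength=n_epochs)
    sums = np.bincount(
        sec_epoch[present], weights=enmo.values[present], minlength=n_epochs
    )
    mean_enmo = np.full(n_epochs, np.nan)
    has = n_present > 0
    mean_enmo[has] = sums[has] / n_present[has]
    df = pd.DataFrame(
        {
            "sed_s": sed,
            "lpa_s": lpa,
            "mvpa_s": mvpa,
            "missing_s": missing,
            "mean_enmo_mg": mean_enmo,
            "valid": missing <= missing_tol_s,
        },
        index=pd.DatetimeIndex(
            grid0 + np.arange(n_epochs) * step, name="epoch_start"
        ),
    )
    return df


def _static_windows(
    stream: RawAccelStream, window_s: int, still_sd_g: float
) -> np.ndarray:
    """Mean vectors of non-overlapping windows whose per-axis SD is low."""
    means = []
    n_win = int(round(window_s * stream.fs))
    for seg in stream.segments:
        if seg.n < n_win:
            continue
        n_full = seg.n // n_win
        blocks = seg.data[: n_full * n_win].reshape(n_full, n_win, 3).astype(np.float64)
        sd = blocks.std(axis=1)
        still = (sd < still_sd_g).all(axis=1)
        if still.any():
            means.append(blocks[still].mean(axis=1))
    if not means:
        return np.empty((0, 3))
    return np.vstack(means)


def calibrate(
    stream: RawAccelStream,
    still_sd_g: float = 0.004,
    window_s: int = 10,
    min_windows: int = 20,
    sphere_crit_g: float = 0.3,
    skip_error_g: float = 0.005,
    n_iter: int = 50,
) -> RawAccelStream:
    """Static-window gain/offset autocalibration.

    Windows of ``window_s`` seconds whose per-axis standard deviation is
    below ``still_sd_g`` are taken as static; a per-axis linear model
    (gain * a + offset) is fitted by iterated least squares so the static
    mean vectors approach unit norm (1 g). The fit requires at least
    ``min_windows`` static windows whose per-axis means reach beyond
    +/- ``sphere_crit_g`` (orientation diversity); otherwise the stream
    is returned unchanged with ``meta['calibrated'] = False``. The
    procedure degrades gracefully and never raises on poor data.
    """
    uncal = replace(stream, meta={**stream.meta, "calibrated": False})
    if not stream.segments or stream.duration_s() < 600:
        return uncal
    pts = _static_windows(stream, window_s, still_sd_g)
    if len(pts) < min_windows:
        return uncal
    spread_ok = all(
        pts[:, ax].min() < -sphere_crit_g and pts[:, ax].max() > sphere_crit_g
        for ax in range(3)
    )
    if not spread_ok:
        return uncal
    start_error = float(np.abs(np.linalg.norm(pts, axis=1) - 1.0).mean())
    if start_error < skip_error_g:
        # already within tolerance: applying no correction avoids letting
        # low-movement (but not perfectly still) windows bias the fit
        meta = {**stream.meta, "calibrated": True, "calibration_applied": False,
                "calibration_error_g": start_error}
        return replace(stream, meta=meta)
    gain = np.ones(3)
    offset = np.zeros(3)
    for _ in range(n_iter):
        cur = pts * gain + offset
        norms = np.linalg.norm(cur, axis=1)
        norms[norms == 0] = 1.0
        target = cur / norms[:, None]
        for ax in range(3):
            A = np.column_stack([cur[:, ax], np.ones(len(cur))])
            slope, intercept = np.linalg.lstsq(A, target[:, ax], rcond=None)[0]
            gain[ax] *= slope
            offset[ax] = offset[ax] * slope + intercept
        if np.abs(norms - 1.0).max() < 1e-10:
            break
    segments = [
        Segment(start=s.start, data=(s.data * gain + offset).astype(s.data.dtype))
        for s in stream.segments
    ]
    meta = {
        **stream.meta,
        "calibrated": True,
        "calibration_gain": gain.copy(),
        "calibration_offset": offset.copy(),
        "calibration_windows": int(len(pts)),
    }
    return RawAccelStream(stream.device_id, stream.fs, segments, meta)
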