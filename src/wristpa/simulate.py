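"""Synthetic study-data generator with analytic ground truth.

Generates everything the validation pipeline consumes: a 62-minute
simulated free-living activity protocol (12 five-minute activities in
three intensity categories separated by two one-minute transits),
multi-day free-living recordings for two co-worn wrist devices (a 25 Hz
test device and a 100 Hz criterion device), paired breath-by-breath
oxygen-uptake data, and sleep / non-wear logs — with per-second
ground-truth intensity labels.

The movement signal is constructed so that ground truth is analytic
rather than empirical: acceleration is a per-bout constant gravity unit
vector scaled by ``1 + m(t)`` with ``m(t) = (e/1000)(1 - cos 2*pi*f*t)``,
``e`` the bout's target ENMO in milli-g and ``f`` an integer frequency in
the 1-3 Hz band of human movement. Because whole cycles fit every
wall-clock second at both sampling rates, the per-second mean ENMO of the
noise-free signal equals the target exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import RawAccelStream, Segment
from .calorimetry import MET_PER_KG, BreathStream
from .config import CutPoints

log = logging.getLogger(__name__)

MS = np.timedelta64(1, "ms")
DEFAULT_SESSION_START = np.datetime64("2021-03-01T10:00:00.000")
DEFAULT_WEEK_START = np.datetime64("2021-03-08T00:00:00.000")


class Intensity(str, Enum):
    SED = "SED"
    LPA = "LPA"
    MVPA = "MVPA"
    TRANSIT = "TRANSIT"


@dataclass(frozen=True)
class ActivityBlock:
    """One protocol activity with its metabolic and acceleration targets.

    ``target_met`` is the steady-state metabolic cost in METs;
    ``target_enmo_mg`` the mean wrist ENMO the block should induce.
    """

    label: str
    intensity_class: Intensity
    duration_s: int
    target_met: float
    target_enmo_mg: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.target_enmo_mg < 0:
            raise ValueError("target ENMO must be non-negative")
        if self.target_met < 0.9:
            raise ValueError("target MET below plausible resting floor (0.9)")

    def induced_class(self, cuts: CutPoints | None = None) -> str:
        """Intensity class the block's target ENMO maps to under the cut-points."""
        cuts = cuts or CutPoints()
        if self.target_enmo_mg < cuts.sed_lpa:
            return "SED"
        if self.target_enmo_mg < cuts.lpa_mvpa:
            return "LPA"
        return "MVPA"


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered activity blocks of the simulated free-living session."""

    blocks: tuple[ActivityBlock, ...]

    @property
    def total_duration_s(self) -> int:
        return sum(b.duration_s for b in self.blocks)

    @property
    def n_activities(self) -> int:
        return sum(1 for b in self.blocks if b.intensity_class is not Intensity.TRANSIT)


def default_protocol() -> ProtocolSchedule:
    """The 62-minute session: 4 sedentary, 4 light, 4 moderate-to-vigorous
    activities of 5 min each, with 1-min transits between categories.

    Per-activity MET and ENMO targets are chosen comfortably inside the
    class bands implied by the default cut-points and MET breakpoints,
    so the induced class of every block matches its category.
    """
    b = ActivityBlock
    sed, lpa, mvpa, tr = Intensity.SED, Intensity.LPA, Intensity.MVPA, Intensity.TRANSIT
    return ProtocolSchedule(
        blocks=(
            b("Resting in the supine position", sed, 300, 1.0, 4.0),
            b("Watching TV in the sitting position", sed, 300, 1.3, 6.0),
            b("Reading books in the sitting position", sed, 300, 1.3, 8.0),
            b("Typing at a computer in the sitting position", sed, 300, 1.4, 12.0),
            b("Transit #1", tr, 60, 1.4, 20.0),
            b("Fidgeting in the standing position", lpa, 300, 1.8, 60.0),
            b("Walking at a casual pace", lpa, 300, 2.0, 70.0),
            b("Housekeeping / setting the table", lpa, 300, 2.5, 85.0),
            b("Exploring / stacking light boxes", lpa, 300, 2.3, 78.0),
            b("Transit #2", tr, 60, 1.4, 20.0),
            b("Walking briskly", mvpa, 300, 3.5, 180.0),
            b("Running at a moderate pace", mvpa, 300, 5.5, 250.0),
            b("Running at a fast pace", mvpa, 300, 8.0, 400.0),
            b("Full body free play", mvpa, 300, 6.5, 320.0),
        )
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    ``noise_sd`` is the per-axis white accelerometer noise in g (the
    2 mg default matches the RMS noise of modern MEMS wrist sensors at
    these bandwidths); ``inter_device_bias`` is a residual z-axis offset
    of the test device after factory calibration. ``body_mass`` defaults
    to the mean body mass of the emulated study population.
    """

    seed: int = 0
    fs_test: float = 25.0
    fs_criterion: float = 100.0
    noise_sd: float = 0.002
    inter_device_bias: float = 0.005
    body_mass: float = 90.1
    breath_interval: tuple[float, float] = (2.0, 4.0)
    vo2_noise_cv: float = 0.08
    onset_tau_s: float = 30.0

    def __post_init__(self) -> None:
        if self.fs_test <= 0 or self.fs_criterion <= 0:
            raise ValueError("sampling rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")


# ---------------------------------------------------------------------------
# free-living week plans


@dataclass(frozen=True)
class Bout:
    """A free-living activity bout (minute-aligned within its day)."""

    start_min: int
    dur_min: int
    intensity: Intensity
    target_enmo_mg: float
    target_met: float
    freq_hz: int
    g_dir: tuple[float, float, float]


@dataclass(frozen=True)
class Gap:
    """A minute-aligned gap: device off wrist (non-wear) or dropout."""

    start_min: int
    dur_min: int
    g_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def end_min(self) -> int:
        return self.start_min + self.dur_min


@dataclass(frozen=True)
class DayPlan:
    waking: tuple[int, int]  # minutes from midnight
    bouts: tuple[Bout, ...]
    nonwear: tuple[Gap, ...] = ()
    dropout: tuple[Gap, ...] = ()  # test device only


@dataclass(frozen=True)
class WeekPlan:
    start: np.datetime64  # midnight of day 0
    days: tuple[DayPlan, ...]

    @property
    def n_days(self) -> int:
        return len(self.days)


def _rand_unit(rng: np.random.Generator) -> tuple[float, float, float]:
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return tuple(float(x) for x in v)


#: per-class time share, bout duration ranges (min) and target ranges used
#: by the free-living plan generator; sedentary-heavy, matching the high
#: SED fraction typical of wrist-based free-living estimates
_CLASS_PROBS = {"SED": 0.60, "LPA": 0.25, "MVPA": 0.15}
_DUR_RANGE = {"SED": (20, 50), "LPA": (5, 15), "MVPA": (3, 10)}
_ENMO_RANGE = {"SED": (3.0, 12.0), "LPA": (55.0, 90.0), "MVPA": (150.0, 380.0)}
_MET_RANGE = {"SED": (1.0, 1.4), "LPA": (1.7, 2.8), "MVPA": (3.2, 7.5)}


def random_week_plan(
    seed: int | np.random.Generator = 0,
    days: int = 7,
    start: np.datetime64 = DEFAULT_WEEK_START,
    waking: tuple[int, int] = (420, 1380),  # 07:00-23:00
    p_nonwear_day: float = 0.4,
    nonwear_dur: tuple[int, int] = (100, 150),
    p_dropout_day: float = 0.5,
    dropout_dur: tuple[int, int] = (10, 30),
) -> WeekPlan:
    """A seeded multi-day free-living plan with known ground truth.

    Each day's waking window is tiled with sedentary / light / MVPA
    bouts; some days carry a long off-wrist (non-wear) gap, and the test
    device additionally suffers short Bluetooth-dropout gaps. All events
    are minute-aligned and gaps never overlap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ws, we = waking
    if not 0 <= ws < we <= 1440:
        raise ValueError("waking window must lie within the day")
    classes = list(_CLASS_PROBS)
    probs = np.array(list(_CLASS_PROBS.values()))
    day_plans = []
    for _ in range(days):
        nonwear: list[Gap] = []
        if rng.random() < p_nonwear_day:
            dur = int(rng.integers(nonwear_dur[0], nonwear_dur[1] + 1))
            dur = min(dur, we - ws)
            start_min = int(rng.integers(ws, we - dur + 1))
            nonwear.append(Gap(start_min, dur, _rand_unit(rng)))
        dropout: list[Gap] = []
        if rng.random() < p_dropout_day:
            dur = int(rng.integers(dropout_dur[0], dropout_dur[1] + 1))
            for _try in range(50):
                start_min = int(rng.integers(ws, we - dur + 1))
                cand = Gap(start_min, dur)
                if all(
                    cand.end_min <= g.start_min or cand.start_min >= g.end_min
                    for g in nonwear
                ):
                    dropout.append(cand)
                    break
        # wear intervals = waking window minus non-wear gaps
        edges = [ws]
        for g in sorted(nonwear, key=lambda g: g.start_min):
            edges += [g.start_min, g.end_min]
        edges.append(we)
        bouts: list[Bout] = []
        for a, bnd in zip(edges[::2], edges[1::2]):
            t = a
            while t < bnd:
                cls = classes[rng.choice(len(classes), p=probs)]
                lo, hi = _DUR_RANGE[cls]
                dur = min(int(rng.integers(lo, hi + 1)), bnd - t)
                bouts.append(
                    Bout(
                        start_min=t,
                        dur_min=dur,
                        intensity=Intensity(cls),
                        target_enmo_mg=float(rng.uniform(*_ENMO_RANGE[cls])),
                        target_met=float(rng.uniform(*_MET_RANGE[cls])),
                        freq_hz=int(rng.integers(1, 4)),
                        g_dir=_rand_unit(rng),
                    )
                )
                t += dur
        day_plans.append(
            DayPlan(
                waking=(ws, we),
                bouts=tuple(bouts),
                nonwear=tuple(nonwear),
                dropout=tuple(dropout),
            )
        )
    return WeekPlan(start=np.datetime64(start, "ms"), days=tuple(day_plans))


# ---------------------------------------------------------------------------
# signal rendering


def _render_motion(
    spans: list[tuple[int, int, float, int, tuple[float, float, float]]],
    total_s: int,
    fs: float,
) -> np.ndarray:
    """Noise-free tri-axial samples for (offset_s, dur_s, enmo_mg, f, g_dir) spans."""
    n = round(total_s * fs)
    data = np.zeros((n, 3))
    for off_s, dur_s, enmo_mg, f_hz, g_dir in spans:
        i0, i1 = round(off_s * fs), round((off_s + dur_s) * fs)
        t = np.arange(i1 - i0) / fs
        m = (enmo_mg / 1000.0) * (1.0 - np.cos(2.0 * np.pi * f_hz * t))
        data[i0:i1] = np.asarray(g_dir) * (1.0 + m)[:, None]
    return data


def _check_gaps(day: DayPlan) -> None:
    gaps = sorted(list(day.nonwear) + list(day.dropout), key=lambda g: g.start_min)
    for a, b in zip(gaps, gaps[1:]):
        if b.start_min < a.end_min:
            raise ValueError(
                f"overlapping gap intervals at minutes {b.start_min} < {a.end_min}"
            )


def simulate_accel_pair(
    schedule_or_plan: ProtocolSchedule | WeekPlan,
    cfg: SimConfig,
    start: np.datetime64 | None = None,
    cuts: CutPoints | None = None,
) -> tuple[RawAccelStream, RawAccelStream, pd.DataFrame]:
    """Co-worn test (25 Hz) and criterion (100 Hz) streams plus ground truth.

    Both devices see the same underlying motion; each gets its own white
    noise, the test device additionally the inter-device z bias and (for
    week plans) its dropout gaps as absent samples. Ground truth is a
    per-second DataFrame with columns ``time, intensity, wear, sleep,
    valid`` where ``intensity`` is the class the signal's target ENMO
    induces under ``cuts`` (None during sleep and non-wear gaps).
    Identical configuration (including the seed) yields identical output.
    """
    cuts = cuts or CutPoints()
    rng_sig = np.random.default_rng([cfg.seed, 11])
    rng_test = np.random.default_rng([cfg.seed, 1])
    rng_crit = np.random.default_rng([cfg.seed, 2])

    if isinstance(schedule_or_plan, ProtocolSchedule):
        sched = schedule_or_plan
        t0 = np.datetime64(start if start is not None else DEFAULT_SESSION_START, "ms")
        spans = []
        off = 0
        sec_class: list[str] = []
        for blk in sched.blocks:
            spans.append(
                (off, blk.duration_s, blk.target_enmo_mg, int(rng_sig.integers(1, 4)), _rand_unit(rng_sig))
            )
            sec_class += [blk.induced_class(cuts)] * blk.duration_s
            off += blk.duration_s
        total = sched.total_duration_s
        streams = []
        for fs, rng, bias in (
            (cfg.fs_test, rng_test, cfg.inter_device_bias),
            (cfg.fs_criterion, rng_crit, 0.0),
        ):
            data = _render_motion(spans, total, fs)
            if cfg.noise_sd > 0:
                data = data + rng.normal(0.0, cfg.noise_sd, data.shape)
            if bias:
                data = data.copy()
                data[:, 2] += bias
            streams.append(data)
        test = RawAccelStream("test", cfg.fs_test, [Segment(t0, streams[0])])
        crit = RawAccelStream("criterion", cfg.fs_criterion, [Segment(t0, streams[1])])
        truth = pd.DataFrame(
            {
                "time": t0 + (np.arange(total) * 1000).astype("timedelta64[ms]"),
                "intensity": pd.Categorical(sec_class),
                "wear": True,
                "sleep": False,
                "valid": True,
            }
        )
        return test, crit, truth

    plan = schedule_or_plan
    t0 = np.datetime64(start if start is not None else plan.start, "ms")
    test_segments: list[Segment] = []
    crit_segments: list[Segment] = []
    n_sec = plan.n_days * 86400
    intensity = np.full(n_sec, -1, dtype=np.int8)
    code = {"SED": 0, "LPA": 1, "MVPA": 2}
    names = np.array(["SED", "LPA", "MVPA"], dtype=object)
    wear = np.zeros(n_sec, dtype=bool)
    sleep = np.ones(n_sec, dtype=bool)
    valid = np.ones(n_sec, dtype=bool)
    for d, day in enumerate(plan.days):
        _check_gaps(day)
        ws, we = day.waking
        day0_s = d * 86400
        sleep[day0_s + ws * 60 : day0_s + we * 60] = False
        wear[day0_s + ws * 60 : day0_s + we * 60] = True
        spans = []
        for b in day.bouts:
            spans.append(
                ((b.start_min - ws) * 60, b.dur_min * 60, b.target_enmo_mg, b.freq_hz, b.g_dir)
            )
            s0 = day0_s + b.start_min * 60
            blk = ActivityBlock(
                "bout", b.intensity, b.dur_min * 60, max(b.target_met, 0.9), b.target_enmo_mg
            )
            intensity[s0 : s0 + b.dur_min * 60] = code[blk.induced_class(cuts)]
        for g in day.nonwear:
            spans.append(((g.start_min - ws) * 60, g.dur_min * 60, 0.0, 1, g.g_dir))
            s0 = day0_s + g.start_min * 60
            wear[s0 : s0 + g.dur_min * 60] = False
        for g in day.dropout:
            s0 = day0_s + g.start_min * 60
            valid[s0 : s0 + g.dur_min * 60] = False
        total = (we - ws) * 60
        day_start = t0 + np.timedelta64(day0_s + ws * 60, "s").astype("timedelta64[ms]")
        # criterion: records the whole waking window
        m_crit = _render_motion(spans, total, cfg.fs_criterion)
        if cfg.noise_sd > 0:
            m_crit += rng_crit.normal(0.0, cfg.noise_sd, m_crit.shape)
        crit_segments.append(Segment(day_start, m_crit.astype(np.float32)))
        # test: same motion at its own rate, bias, dropout samples removed
        m_test = _render_motion(spans, total, cfg.fs_test)
        if cfg.noise_sd > 0:
            m_test += rng_test.normal(0.0, cfg.noise_sd, m_test.shape)
        m_test[:, 2] += cfg.inter_device_bias
        m_test = m_test.astype(np.float32)
        cut_edges = [0]
        for g in sorted(day.dropout, key=lambda g: g.start_min):
            cut_edges += [(g.start_min - ws) * 60, (g.end_min - ws) * 60]
        cut_edges.append(total)
        for a, bnd in zip(cut_edges[::2], cut_edges[1::2]):
            if bnd <= a:
                continue
            i0, i1 = round(a * cfg.fs_test), round(bnd * cfg.fs_test)
            seg_start = day_start + np.timedelta64(a, "s").astype("timedelta64[ms]")
            test_segments.append(Segment(seg_start, m_test[i0:i1]))
    truth = pd.DataFrame(
        {
            "time": t0 + (np.arange(n_sec, dtype=np.int64) * 1000).astype("timedelta64[ms]"),
            "intensity": pd.Categorical.from_codes(intensity, categories=names),
            "wear": wear,
            "sleep": sleep,
            "valid": valid,
        }
    )
    test = RawAccelStream("test", cfg.fs_test, test_segments)
    crit = RawAccelStream("criterion", cfg.fs_criterion, crit_segments)
    return test, crit, truth


def sleep_intervals(plan: WeekPlan) -> list[tuple[np.datetime64, np.datetime64]]:
    """The plan's sleep windows as absolute (start, end) timestamps."""
    out = []
    day_ms = np.timedelta64(86400_000, "ms")
    for d, day in enumerate(plan.days):
        ws, we = day.waking
        base = plan.start + d * day_ms
        if ws > 0:
            out.append((base, base + np.timedelta64(ws * 60_000, "ms")))
        if we < 1440:
            out.append((base + np.timedelta64(we * 60_000, "ms"), base + day_ms))
    return out


def truth_minutes(truth: pd.DataFrame) -> pd.Series:
    """Ground-truth analysis-set minutes per class (SED/LPA/MVPA).

    A minute counts for a class when all 60 of its seconds are worn,
    awake, valid, and labelled with that class.
    """
    n = len(truth) - len(truth) % 60
    codes = truth["intensity"].cat.codes.to_numpy()[:n].reshape(-1, 60)
    ok = (
        truth["wear"].to_numpy()[:n]
        & ~truth["sleep"].to_numpy()[:n]
        & truth["valid"].to_numpy()[:n]
    ).reshape(-1, 60)
    names = list(truth["intensity"].cat.categories)
    uniform = (codes == codes[:, :1]).all(axis=1) & ok.all(axis=1) & (codes[:, 0] >= 0)
    counts = {c: 0 for c in ["SED", "LPA", "MVPA"]}
    for ci, name in enumerate(names):
        counts[name] = int((uniform & (codes[:, 0] == ci)).sum())
    return pd.Series(counts, name="minutes")


# ---------------------------------------------------------------------------
# breath simulation


def simulate_breaths(
    schedule: ProtocolSchedule,
    cfg: SimConfig,
    start: np.datetime64 | None = None,
) -> BreathStream:
    """Irregular breath-by-breath VO2 for the protocol session.

    VO2 fluctuates (coefficient of variation ``vo2_noise_cv``) around
    ``target_met * 3.5 * body_mass`` with a first-order onset lag of time
    constant ``onset_tau_s`` at block transitions; the session starts at
    the first block's steady state.
    """
    if cfg.body_mass <= 0:
        raise ValueError("body mass must be positive")
    rng = np.random.default_rng([cfg.seed, 3])
    total = schedule.total_duration_s
    lo, hi = cfg.breath_interval
    times = []
    t = 0.0
    while t < total:
        times.append(t)
        t += rng.uniform(lo, hi)
    t_arr = np.array(times)
    # block entry METs under first-order kinetics
    starts, targets = [], []
    off = 0
    for blk in schedule.blocks:
        starts.append(off)
        targets.append(blk.target_met)
        off += blk.duration_s
    entry = [targets[0]]
    for k in range(1, len(targets)):
        dur = starts[k] - starts[k - 1]
        prev = targets[k - 1] + (entry[k - 1] - targets[k - 1]) * np.exp(
            -dur / cfg.onset_tau_s
        )
        entry.append(prev)
    idx = np.searchsorted(starts, t_arr, side="right") - 1
    tgt = np.array(targets)[idx]
    ent = np.array(entry)[idx]
    met = tgt + (ent - tgt) * np.exp(-(t_arr - np.array(starts)[idx]) / cfg.onset_tau_s)
    vo2 = met * MET_PER_KG * cfg.body_mass
    if cfg.vo2_noise_cv > 0:
        vo2 = vo2 * (1.0 + cfg.vo2_noise_cv * rng.standard_normal(len(vo2)))
        np.clip(vo2, 0.0, None, out=vo2)
    t0 = np.datetime64(start if start is not None else DEFAULT_SESSION_START, "ms")
    stamps = t0 + np.round(t_arr * 1000).astype("timedelta64[ms]")
    return BreathStream(times=stamps, vo2=vo2, body_mass_kg=cfg.body_mass)


# ---------------------------------------------------------------------------
# fixture studies on disk


def _write_csv(df: pd.DataFrame, path: Path, float_format: str = "%.5f") -> None:
    try:
        df.to_csv(path, index=False, float_format=float_format)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing {path}: {exc}") from exc


def _accel_frame(stream: RawAccelStream) -> pd.DataFrame:
    df = stream.to_frame()
    df["timestamp"] = np.datetime_as_string(
        df["timestamp"].to_numpy().astype("datetime64[ms]"), unit="ms"
    )
    return df


def _breath_frame(breaths: BreathStream) -> pd.DataFrame:
    df = breaths.to_frame()
    df["timestamp"] = np.datetime_as_string(df["timestamp"].to_numpy(), unit="ms")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_study(
    outdir: str | Path,
    n_participants: int,
    cfg: SimConfig,
    plan_kwargs: dict | None = None,
) -> dict:
    """Write a complete synthetic study to ``outdir``; returns the manifest.

    Layout: ``participants.csv`` and ``log.csv`` at the top level, then
    one directory per participant with five data files (session and week
    raw CSVs for both devices, session breath CSV) plus a ground-truth
    CSV of true analysis-set minutes per class. The manifest (also
    written as ``manifest.json``) records the seed and a SHA-256 per
    file, so reruns with the same configuration are verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan_kwargs = plan_kwargs or {}
    rng_mass = np.random.default_rng([cfg.seed, 999])
    manifest: dict = {"seed": cfg.seed, "participants": [], "files": {}}
    part_rows = []
    log_rows = []

    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        child_seed = int(np.random.default_rng([cfg.seed, 1000 + i]).integers(2**31))
        mass = float(np.clip(rng_mass.normal(90.1, 12.5), 45.0, 160.0).round(1))
        cfg_i = replace(cfg, seed=child_seed, body_mass=mass)
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        part_rows.append({"participant": pid, "body_mass_kg": mass})
        manifest["participants"].append({"id": pid, "seed": child_seed})

        sched = default_protocol()
        s_test, s_crit, s_truth = simulate_accel_pair(sched, cfg_i)
        breaths = simulate_breaths(sched, cfg_i)
        plan = random_week_plan(seed=child_seed, **plan_kwargs)
        w_test, w_crit, w_truth = simulate_accel_pair(plan, cfg_i)

        _write_csv(_accel_frame(s_test), pdir / "session_test.csv")
        _write_csv(_accel_frame(s_crit), pdir / "session_criterion.csv")
        _write_csv(_breath_frame(breaths), pdir / "session_breaths.csv", "%.3f")
        _write_csv(_accel_frame(w_test), pdir / "week_test.csv")
        _write_csv(_accel_frame(w_crit), pdir / "week_criterion.csv")

        gt = []
        for scope, truth in (("session", s_truth), ("week", w_truth)):
            mins = truth_minutes(truth)
            for cls, val in mins.items():
                gt.append({"scope": scope, "intensity": cls, "minutes": val})
        _write_csv(pd.DataFrame(gt), pdir / "ground_truth.csv")

        day_ms = np.timedelta64(86400_000, "ms")
        for d, day in enumerate(plan.days):
            date = str((plan.start + d * day_ms).astype("datetime64[D]"))
            ws, we = day.waking
            if ws > 0:
                log_rows.append(
                    {"participant": pid, "date": date,
                     "sleep_start": "00:00", "sleep_end": f"{ws // 60:02d}:{ws % 60:02d}",
                     "nonwear_start": "", "nonwear_end": ""}
                )
            if we < 1440:
                # crosses midnight: end before start means "next day"
                log_rows.append(
                    {"participant": pid, "date": date,
                     "sleep_start": f"{we // 60:02d}:{we % 60:02d}", "sleep_end": "00:00",
                     "nonwear_start": "", "nonwear_end": ""}
                )
            for g in day.nonwear:
                log_rows.append(
                    {"participant": pid, "date": date, "sleep_start": "", "sleep_end": "",
                     "nonwear_start": f"{g.start_min // 60:02d}:{g.start_min % 60:02d}",
                     "nonwear_end": f"{g.end_min // 60:02d}:{g.end_min % 60:02d}"}
                )

    _write_csv(pd.DataFrame(part_rows, columns=["participant", "body_mass_kg"]),
               outdir / "participants.csv")
    _write_csv(
        pd.DataFrame(
            log_rows,
            columns=["participant", "date", "sleep_start", "sleep_end",
                     "nonwear_start", "nonwear_end"],
        ),
        outdir / "log.csv",
    )

    for path in sorted(outdir.rglob("*.csv")):
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote fixture study: %d participants at %s", n_participants, outdir)
    return manifest
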