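"""End-to-end orchestration: raw streams to summaries and agreement reports.

These functions chain the module stages — calibration, ENMO, per-second
classification, 60-s epochs, wear/sleep/valid masking, calorimetry
epochs, merging, summarising — exactly as the CLI runs them, and are the
same code paths the test suite exercises in memory.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io
from .accelerometry import (
    RawAccelStream,
    calibrate,
    classify_seconds,
    collapse_to_epochs,
    compute_enmo,
)
from .agreement import agreement_report
from .calorimetry import BreathStream, collapse_breaths
from .config import StudyConfig
from .nonwear import build_mask
from .summaries import merge_streams, summarize

log = logging.getLogger(__name__)

TEST, CRITERION, CALORIMETRY = "TEST", "CRITERION", "CALORIMETRY"

# device sampling rates of the emulated study hardware
FS_TEST = 25.0
FS_CRITERION = 100.0


def process_accel(stream: RawAccelStream, config: StudyConfig) -> pd.DataFrame:
    """Raw stream → calibrated → per-second ENMO/classes → 60-s epochs."""
    cal = calibrate(
        stream,
        still_sd_g=config.calib_still_sd_g,
        window_s=config.calib_window_s,
        min_windows=config.calib_min_windows,
        sphere_crit_g=config.calib_sphere_crit_g,
    )
    enmo = compute_enmo(cal, min_coverage=config.second_coverage_min)
    classes = classify_seconds(enmo, config.cut_points)
    return collapse_to_epochs(
        classes, enmo, epoch_len_s=config.epoch_len_s,
        missing_tol_s=config.epoch_missing_tol_s,
    )


def process_breaths(breaths: BreathStream, config: StudyConfig) -> pd.DataFrame:
    return collapse_breaths(
        breaths,
        intermediate_s=config.breath_bin_s,
        final_s=config.epoch_len_s,
        min_bins=config.min_bins_per_min,
        met_breakpoints=config.met_breakpoints,
    )


def analyze_pair(
    test_stream: RawAccelStream,
    criterion_stream: RawAccelStream,
    config: StudyConfig,
    sleep_intervals: list[tuple] | None = None,
    breaths: BreathStream | None = None,
    period: str = "per-day",
    participant: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process both devices (and optionally breaths) into summaries.

    Returns ``(summary, mask)``; the summary has one row per source.
    """
    epochs_test = process_accel(test_stream, config)
    epochs_crit = process_accel(criterion_stream, config)
    mask = build_mask(
        epochs_test,
        epochs_crit,
        sleep_intervals=sleep_intervals,
        window_min=config.choi.window_min,
        spike_tol_min=config.choi.spike_tol_min,
        spike_win_min=config.choi.spike_win_min,
        stillness_floor_mg=config.stillness_floor_mg,
    )
    sources = {TEST: epochs_test, CRITERION: epochs_crit}
    if breaths is not None:
        sources[CALORIMETRY] = process_breaths(breaths, config)
    merged = merge_streams(sources, mask)
    summary = summarize(
        merged, period=period, participant=participant,
        min_valid_day_min=config.min_valid_day_min,
    )
    return summary, mask


def process_study_dir(
    indir: str | Path, config: StudyConfig, outdir: str | Path
) -> pd.DataFrame:
    """Process a fixture-study directory into epoch and summary CSVs.

    Expects the layout written by the synthetic-data generator:
    ``participants.csv``, ``log.csv`` and per-participant directories
    with session/week raw CSVs. A missing breath file only skips the
    calorimetry source for that participant.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants = io.read_participants(indir / "participants.csv")
    logs = (
        io.read_sleep_log(indir / "log.csv") if (indir / "log.csv").exists() else {}
    )
    all_rows = []
    for _, row in participants.iterrows():
        pid, mass = str(row["participant"]), float(row["body_mass_kg"])
        pdir = indir / pid
        sleep = logs.get(pid, {}).get("sleep", [])

        for scope, period in (("session", "per-session"), ("week", "per-day")):
            test_path = pdir / f"{scope}_test.csv"
            crit_path = pdir / f"{scope}_criterion.csv"
            if not test_path.exists() or not crit_path.exists():
                continue
            test = io.read_accel_csv(test_path, "test", FS_TEST)
            crit = io.read_accel_csv(crit_path, "criterion", FS_CRITERION)
            breaths = None
            if scope == "session":
                bpath = pdir / "session_breaths.csv"
                if bpath.exists():
                    breaths = io.read_breath_csv(bpath, mass)
                else:
                    log.warning("%s: no breath file; calorimetry stage skipped", pid)
            summary, mask = analyze_pair(
                test, crit, config,
                sleep_intervals=sleep if scope == "week" else None,
                breaths=breaths, period=period, participant=pid,
            )
            mask_out = outdir / f"{pid}_{scope}_mask.csv"
            mask.astype(int).to_csv(mask_out)
            all_rows.append(summary)
    if not all_rows:
        raise ValueError(f"no processable participants found under {indir}")
    summaries = pd.concat(all_rows, ignore_index=True)
    io.write_summary_csv(summaries, outdir / "summaries.csv")
    return summaries


def validate_summaries(summaries: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Agreement report: test vs criterion device and test vs calorimetry."""
    reports = []
    for crit_dev, period in (
        (CRITERION, "per-day"),
        (CRITERION, "per-session"),
        (CALORIMETRY, "per-session"),
    ):
        have = set(summaries.loc[summaries["period"] == period, "device"])
        if TEST in have and crit_dev in have:
            reports.append(
                agreement_report(
                    summaries, crit_dev, TEST, period,
                    ci_level=config.ci_level,
                    ez_granularity=config.ez_granularity_pct,
                )
            )
    if not reports:
        raise ValueError("summaries contain no comparable device pair")
    return pd.concat(reports, ignore_index=True)
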