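"""The synthetic protocol/week generator and its determinism contracts."""
import json

import numpy as np
import pytest

import wristpa as w
from wristpa.simulate import DayPlan, Gap, WeekPlan

from conftest import SMALL_PLAN_KWARGS


class TestDefaultProtocol:
    def test_total_duration_62_minutes(self):
        assert w.default_protocol().total_duration_s == 3720

    def test_twelve_activities_plus_two_transits(self):
        p = w.default_protocol()
        assert p.n_activities == 12
        assert len(p.blocks) == 14

    def test_first_four_blocks_sedentary(self):
        p = w.default_protocol()
        assert all(b.intensity_class is w.Intensity.SED for b in p.blocks[:4])

    def test_block_structure(self):
        p = w.default_protocol()
        durs = [b.duration_s for b in p.blocks]
        assert durs == [300] * 4 + [60] + [300] * 4 + [60] + [300] * 4

    def test_targets_induce_their_category(self, study_config):
        """Every activity block's target ENMO and MET map back to the
        block's own intensity category under the default thresholds."""
        for b in w.default_protocol().blocks:
            if b.intensity_class is w.Intensity.TRANSIT:
                continue
            assert b.induced_class(study_config.cut_points) == b.intensity_class.value
            met_cls = w.classify_met(b.target_met, study_config.met_breakpoints)
            folded = {"SED": "SED", "LPA": "LPA", "MPA": "MVPA", "VPA": "MVPA"}[met_cls]
            assert folded == b.intensity_class.value

    def test_block_invariants_enforced(self):
        with pytest.raises(ValueError):
            w.ActivityBlock("x", w.Intensity.SED, 0, 1.0, 5.0)
        with pytest.raises(ValueError):
            w.ActivityBlock("x", w.Intensity.SED, 60, 0.5, 5.0)


class TestAccelPair:
    def test_pure_gravity_block_is_still(self):
        blocks = (w.ActivityBlock("rest", w.Intensity.SED, 120, 1.0, 0.0),)
        cfg = w.SimConfig(seed=1, noise_sd=0.0, inter_device_bias=0.0)
        test, crit, _ = w.simulate_accel_pair(w.ProtocolSchedule(blocks), cfg)
        for s in (test, crit):
            e = w.compute_enmo(s)
            assert np.nanmax(e.values) <= 1.0  # <= 1 mg

    def test_sample_counts_match_rates(self):
        cfg = w.SimConfig(seed=1)
        sched = w.default_protocol()
        test, crit, _ = w.simulate_accel_pair(sched, cfg)
        dur = sched.total_duration_s
        assert crit.n_samples == int(np.ceil(dur * cfg.fs_criterion))
        assert test.n_samples == int(np.ceil(dur * cfg.fs_test))

    def test_per_second_enmo_equals_target(self):
        """Noise-free rendering hits the analytic per-second mean exactly."""
        blocks = (
            w.ActivityBlock("a", w.Intensity.LPA, 60, 2.0, 70.0),
            w.ActivityBlock("b", w.Intensity.MVPA, 60, 4.0, 250.0),
        )
        cfg = w.SimConfig(seed=2, noise_sd=0.0, inter_device_bias=0.0)
        test, crit, _ = w.simulate_accel_pair(w.ProtocolSchedule(blocks), cfg)
        for s in (test, crit):
            e = w.compute_enmo(s)
            assert e.values[:60] == pytest.approx(70.0, abs=1e-6)
            assert e.values[60:120] == pytest.approx(250.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        cfg = w.SimConfig(seed=9)
        a = w.simulate_accel_pair(w.default_protocol(), cfg)
        b = w.simulate_accel_pair(w.default_protocol(), cfg)
        for s1, s2 in zip(a[:2], b[:2]):
            assert all(
                np.array_equal(x.data, y.data) and x.start == y.start
                for x, y in zip(s1.segments, s2.segments)
            )

    def test_overlapping_gaps_rejected(self):
        day = DayPlan(
            waking=(480, 600),
            bouts=(),
            nonwear=(Gap(500, 30),),
            dropout=(Gap(520, 20),),
        )
        plan = WeekPlan(start=np.datetime64("2021-03-08T00:00:00.000"), days=(day,))
        with pytest.raises(ValueError, match="overlap"):
            w.simulate_accel_pair(plan, w.SimConfig(seed=1))

    def test_dropout_only_affects_test_stream(self, small_week_plan):
        cfg = w.SimConfig(seed=7)
        test, crit, truth = w.simulate_accel_pair(small_week_plan, cfg)
        day = small_week_plan.days[0]
        assert day.dropout  # plan guarantees one
        assert len(test.segments) == len(crit.segments) + len(day.dropout)
        lost = sum(g.dur_min for g in day.dropout) * 60
        assert crit.n_samples - 0 == round(
            (day.waking[1] - day.waking[0]) * 60 * cfg.fs_criterion
        )
        assert test.n_samples == round(
            ((day.waking[1] - day.waking[0]) * 60 - lost) * cfg.fs_test
        )

    def test_truth_accounts_every_second(self, small_week_plan):
        _, _, truth = w.simulate_accel_pair(small_week_plan, w.SimConfig(seed=7))
        assert len(truth) == small_week_plan.n_days * 86400
        waking = truth[~truth["sleep"]]
        assert waking["intensity"].notna().sum() == sum(
            b.dur_min * 60 for d in small_week_plan.days for b in d.bouts
        )


class TestBreaths:
    def test_steady_state_resting_vo2(self):
        blocks = (w.ActivityBlock("rest", w.Intensity.SED, 300, 1.0, 5.0),)
        cfg = w.SimConfig(seed=3, vo2_noise_cv=0.0, body_mass=70.0)
        bs = w.simulate_breaths(w.ProtocolSchedule(blocks), cfg)
        assert bs.vo2 == pytest.approx(245.0)

    def test_steady_state_three_met(self):
        blocks = (w.ActivityBlock("walk", w.Intensity.MVPA, 600, 3.0, 150.0),)
        cfg = w.SimConfig(seed=3, vo2_noise_cv=0.0, body_mass=70.0)
        bs = w.simulate_breaths(w.ProtocolSchedule(blocks), cfg)
        assert bs.vo2 == pytest.approx(735.0)

    def test_onset_lag_decays_toward_target(self):
        blocks = (
            w.ActivityBlock("rest", w.Intensity.SED, 300, 1.0, 5.0),
            w.ActivityBlock("run", w.Intensity.MVPA, 300, 6.0, 300.0),
        )
        cfg = w.SimConfig(seed=3, vo2_noise_cv=0.0, body_mass=70.0, onset_tau_s=30.0)
        bs = w.simulate_breaths(w.ProtocolSchedule(blocks), cfg)
        rel = (bs.times - bs.times[0]) / np.timedelta64(1, "s")
        early = bs.vo2[(rel >= 300) & (rel < 310)]
        late = bs.vo2[rel > 590]
        assert early.max() < 6.0 * 3.5 * 70.0 * 0.8  # still rising
        assert late.min() > 6.0 * 3.5 * 70.0 * 0.99  # settled within 1%

    def test_reproducible(self):
        cfg = w.SimConfig(seed=5)
        a = w.simulate_breaths(w.default_protocol(), cfg)
        b = w.simulate_breaths(w.default_protocol(), cfg)
        assert np.array_equal(a.vo2, b.vo2) and np.array_equal(a.times, b.times)


class TestFixtureStudy:
    def test_layout_and_manifest(self, fixture_study):
        outdir, manifest = fixture_study
        for pid in ("P01", "P02"):
            pdir = outdir / pid
            data_files = [
                "session_test.csv", "session_criterion.csv", "session_breaths.csv",
                "week_test.csv", "week_criterion.csv",
            ]
            for f in data_files + ["ground_truth.csv"]:
                assert (pdir / f).exists(), f"{pid}/{f}"
        assert (outdir / "participants.csv").exists()
        assert (outdir / "log.csv").exists()
        on_disk = json.loads((outdir / "manifest.json").read_text())
        assert on_disk["files"] == manifest["files"]

    def test_rerun_is_byte_identical(self, fixture_study, tmp_path):
        _, manifest = fixture_study
        again = w.write_fixture_study(
            tmp_path / "again", 2, w.SimConfig(seed=11), plan_kwargs=SMALL_PLAN_KWARGS
        )
        assert again["files"] == manifest["files"]

    def test_zero_participants_is_empty_not_error(self, tmp_path):
        manifest = w.write_fixture_study(tmp_path / "empty", 0, w.SimConfig(seed=1))
        assert manifest["participants"] == []
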