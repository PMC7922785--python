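"""Paired agreement statistics and the minimum equivalence zone."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wristpa as w
from wristpa.agreement import agreement_report, compute_agreement

RNG = np.random.default_rng(8)


class TestPearson:
    def test_perfect_agreement(self):
        c = np.array([1.0, 2, 3, 4, 5])
        r, p = w.pearson_r(c, c)
        assert r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        c = np.array([1.0, 2, 3, 4, 5])
        r, _ = w.pearson_r(c, -c)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        c = np.array([2.0, 4.0, 5.0, 7.0, 11.0])
        t = np.array([1.0, 5.0, 4.0, 8.0, 9.0])
        # direct product-moment formula
        num = ((c - c.mean()) * (t - t.mean())).sum()
        den = math.sqrt(((c - c.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum())
        r, _ = w.pearson_r(c, t)
        assert abs(r - num / den) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            w.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMeanDifferenceAndMape:
    def test_sign_convention_criterion_minus_test(self):
        # group means 237.1 (criterion) and 242.8 (test) -> -5.7
        md, _ = w.mean_difference([237.1, 237.1], [242.8, 242.8])
        assert md == pytest.approx(-5.7)

    def test_positive_difference(self):
        md, _ = w.mean_difference([15.3, 15.3], [8.5, 8.5])
        assert md == pytest.approx(6.8)

    def test_identical_series_zero_diff_zero_se(self):
        md, se = w.mean_difference([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert md == 0.0 and se == 0.0

    def test_mape_identical_is_zero(self):
        assert w.mape([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_mape_uniform_ten_percent(self):
        c = np.array([10.0, 50.0, 120.0])
        assert w.mape(c, 1.1 * c) == pytest.approx(10.0)

    def test_mape_participant_level(self):
        assert w.mape([10.0, 20.0], [5.0, 30.0]) == pytest.approx(50.0)

    def test_mape_drops_zero_criterion_with_warning(self):
        with pytest.warns(UserWarning, match="zero criterion"):
            got = w.mape([0.0, 10.0], [5.0, 11.0])
        assert got == pytest.approx(10.0)

    def test_mape_all_zero_criterion_rejected(self):
        with pytest.raises(ValueError):
            w.mape([0.0, 0.0], [1.0, 2.0])


class TestBlandAltman:
    def test_constant_difference_zero_width(self):
        bias, lo, hi, _ = w.bland_altman([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert bias == pytest.approx(1.0) and lo == pytest.approx(hi)

    def test_hand_computed_two_pairs(self):
        # d = (-1, 1): bias 0, LoA = +/- 1.96 * sqrt(2)
        bias, lo, hi, pts = w.bland_altman([1.0, 3.0], [2.0, 2.0])
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * math.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * math.sqrt(2.0))
        assert list(pts["mean"]) == [1.5, 2.5]

    def test_sign_flip_negates_bias_keeps_width(self):
        c = RNG.uniform(10, 50, 12)
        t = c + RNG.normal(0, 3, 12)
        b1, lo1, hi1, _ = w.bland_altman(c, t)
        b2, lo2, hi2, _ = w.bland_altman(t, c)
        assert b2 == pytest.approx(-b1)
        assert (hi2 - lo2) == pytest.approx(hi1 - lo1)

    def test_bias_equals_mean_difference(self):
        c = RNG.uniform(0, 100, 15)
        t = RNG.uniform(0, 100, 15)
        assert w.bland_altman(c, t)[0] == w.mean_difference(c, t)[0]


class TestCiMean:
    def test_constant_values_zero_width(self):
        lo, hi = w.ci90_mean([5.0, 5.0, 5.0])
        assert lo == hi == pytest.approx(5.0)

    def test_closed_form_n4(self):
        # mean 2.5, SD sqrt(5/3), t(0.95, 3) = 2.3534
        vals = [1.0, 2.0, 3.0, 4.0]
        half = 2.3534 * math.sqrt(5.0 / 3.0) / 2.0
        lo, hi = w.ci90_mean(vals)
        assert lo == pytest.approx(2.5 - half, abs=1e-4)
        assert hi == pytest.approx(2.5 + half, abs=1e-4)

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30))
    def test_contains_sample_mean(self, vals):
        lo, hi = w.ci90_mean(vals)
        m = float(np.mean(vals))
        assert lo - 1e-9 <= m <= hi + 1e-9


class TestEquivalenceZone:
    @pytest.mark.parametrize(
        "mean,lo,hi,expected",
        [
            (237.1, 198.18, 275.7, 16.5),
            (38.6, 29.51, 40.7, 23.6),
            (65.0, 49.35, 69.87, 24.1),
            (32.8, 27.06, 29.25, 17.5),
            # from printed inputs the minimal zone is 48.5 (containment
            # holds at 48.5 and fails at 48.4)
            (15.3, 7.88, 9.2, 48.5),
        ],
    )
    def test_worked_examples(self, mean, lo, hi, expected):
        ez, ez_lo, ez_hi = w.minimum_equivalence_zone(mean, lo, hi)
        assert ez == pytest.approx(expected, abs=1e-9)
        assert ez_lo == pytest.approx(mean * (1 - ez / 100))
        assert ez_hi == pytest.approx(mean * (1 + ez / 100))

    def test_degenerate_ci_gives_zero(self):
        assert w.minimum_equivalence_zone(40.0, 40.0, 40.0)[0] == 0.0

    def test_equivalence_at_known_bounds(self):
        assert w.equivalence_at(237.1, 198.18, 275.7, 16.5)
        assert not w.equivalence_at(237.1, 198.18, 275.7, 16.4)
        assert w.equivalence_at(50.0, 20.0, 80.0, 100.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            w.minimum_equivalence_zone(0.0, -1.0, 1.0)

    @given(
        mean=st.floats(0.5, 500),
        lo_off=st.floats(-200, 200),
        width=st.floats(0, 200),
    )
    def test_minimality_property(self, mean, lo_off, width):
        """The returned zone contains the CI; one granule less does not."""
        mean = round(mean, 3)
        lo = round(mean + lo_off, 3)
        hi = round(lo + width, 3)
        ez, _, _ = w.minimum_equivalence_zone(mean, lo, hi, granularity=0.1)
        assert w.equivalence_at(mean, lo, hi, ez)
        if ez > 0:
            assert not w.equivalence_at(mean, lo, hi, ez - 0.1)


class TestComputeAgreementAndReport:
    def test_order_invariance(self):
        c = RNG.uniform(10, 60, 10)
        t = c + RNG.normal(0, 2, 10)
        perm = RNG.permutation(10)
        a = compute_agreement(c, t)
        b = compute_agreement(c[perm], t[perm])
        assert a.r == pytest.approx(b.r)
        assert a.mape == pytest.approx(b.mape)
        assert a.ez_pct == pytest.approx(b.ez_pct)

    def test_single_participant_yields_nans_not_errors(self):
        res = compute_agreement([10.0], [12.0])
        assert math.isnan(res.r) and math.isnan(res.se_diff)
        assert math.isnan(res.ez_pct)
        assert res.mape == pytest.approx(20.0)

    def test_report_rows_per_class(self):
        import pandas as pd

        rows = []
        for i in range(6):
            base = dict(participant=f"P{i}", period="per-day")
            c = {"sed_min": 200 + i * 5, "lpa_min": 30 + i, "mvpa_min": 20 + i,
                 "tpa_min": 50 + 2 * i, "wear_min": 300.0}
            rows.append({**base, "device": "CRITERION", **c})
            rows.append({**base, "device": "TEST",
                         **{k: v * 1.05 for k, v in c.items()}})
        rep = agreement_report(pd.DataFrame(rows), "CRITERION", "TEST", "per-day")
        assert list(rep["intensity"]) == ["SED", "LPA", "MVPA", "TPA"]
        assert rep["mape"].to_numpy() == pytest.approx(5.0)
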