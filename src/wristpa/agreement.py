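"""Paired-method agreement statistics for activity-monitor validation.

For each intensity class, per-participant estimates from a test method
are compared with a criterion method via Pearson correlation, mean
difference (criterion − test) with its standard error, mean absolute
percent error (MAPE, participant-level), Bland–Altman bias and 95%
limits of agreement, the t-based 90% CI of the test-method mean, and an
equivalence-zone analysis: the minimum percentage EZ around the
criterion mean that contains the test method's 90% CI.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AgreementResult:
    """All paired statistics for one (comparison, intensity class)."""

    n: int
    crit_mean: float
    test_mean: float
    r: float
    r_pvalue: float
    mean_diff: float
    se_diff: float
    mape: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    ci_low: float
    ci_high: float
    ez_pct: float
    ez_low: float
    ez_high: float


def _pairs(criterion, test) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(criterion, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError("criterion and test must be equal-length 1-D arrays")
    return c, t


def pearson_r(criterion, test) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n−2 df)."""
    c, t = _pairs(criterion, test)
    if len(c) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(c) == 0 or np.ptp(t) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    res = stats.pearsonr(c, t)
    return float(res.statistic), float(res.pvalue)


def mean_difference(criterion, test) -> tuple[float, float]:
    """Mean of criterion − test and its standard error SD/sqrt(n)."""
    c, t = _pairs(criterion, test)
    if len(c) < 2:
        raise ValueError("mean difference needs at least 2 pairs")
    d = c - t
    return float(d.mean()), float(d.std(ddof=1) / math.sqrt(len(d)))


def mape(criterion, test) -> float:
    """Participant-level mean absolute percent error vs the criterion.

    MAPE = mean_i |c_i − t_i| / c_i × 100. Pairs with a zero criterion
    value are dropped with a warning; an all-zero criterion is an error.
    """
    c, t = _pairs(criterion, test)
    keep = c != 0
    if not keep.any():
        raise ValueError("MAPE undefined: all criterion values are zero")
    if not keep.all():
        warnings.warn(
            f"MAPE: dropping {int((~keep).sum())} pair(s) with zero criterion value",
            stacklevel=2,
        )
    c, t = c[keep], t[keep]
    return float(np.mean(np.abs(c - t) / c) * 100.0)


def bland_altman(criterion, test):
    """Bland–Altman bias and 95% limits of agreement.

    Differences d = criterion − test; bias = mean(d); limits of
    agreement = bias ± 1.96 × SD(d) (sample SD). Returns
    ``(bias, loa_low, loa_high, points)`` where ``points`` has one row
    per pair with the pair mean (x) and difference (y).
    """
    c, t = _pairs(criterion, test)
    if len(c) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = c - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    points = pd.DataFrame({"mean": (c + t) / 2.0, "diff": d})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, points


def ci_mean(values, level: float = 0.90) -> tuple[float, float]:
    """Two-sided t confidence interval of the mean: m ± t(q, n−1)·SD/√n."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CI needs at least 2 values")
    m = float(v.mean())
    half = float(
        stats.t.ppf(0.5 + level / 2.0, len(v) - 1) * v.std(ddof=1) / math.sqrt(len(v))
    )
    return m - half, m + half


def ci90_mean(values) -> tuple[float, float]:
    """The 90% t confidence interval of the mean."""
    return ci_mean(values, level=0.90)


def minimum_equivalence_zone(
    crit_mean: float,
    ci_low: float,
    ci_high: float,
    granularity: float = 0.1,
) -> tuple[float, float, float]:
    """Smallest percentage equivalence zone containing a confidence interval.

    Returns ``(ez_pct, ez_low, ez_high)`` where ``ez_pct`` is the
    smallest multiple of ``granularity`` (in percent) such that
    ``[ci_low, ci_high]`` lies within ``crit_mean × (1 ± ez_pct/100)`` —
    i.e. the ceiling to the granularity of
    ``100 × max(crit_mean − ci_low, ci_high − crit_mean) / crit_mean``,
    floored at zero.
    """
    if crit_mean <= 0:
        raise ValueError("criterion mean must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    need = max(crit_mean - ci_low, ci_high - crit_mean, 0.0) / crit_mean * 100.0
    steps = need / granularity
    ez_pct = math.ceil(steps - 1e-9 * max(1.0, steps)) * granularity
    # clean float representation at the granularity's decimals
    decimals = max(0, -int(math.floor(math.log10(granularity))))
    ez_pct = round(ez_pct, decimals + 3)
    ez_low = crit_mean * (1.0 - ez_pct / 100.0)
    ez_high = crit_mean * (1.0 + ez_pct / 100.0)
    return ez_pct, ez_low, ez_high


def equivalence_at(
    crit_mean: float, ci_low: float, ci_high: float, ez_pct: float
) -> bool:
    """True iff the CI lies inside the ±``ez_pct``% zone around the mean."""
    if crit_mean <= 0:
        raise ValueError("criterion mean must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    need = max(crit_mean - ci_low, ci_high - crit_mean, 0.0) / crit_mean * 100.0
    return need <= ez_pct + 1e-9 * max(1.0, need)


def compute_agreement(
    criterion, test, ci_level: float = 0.90, ez_granularity: float = 0.1
) -> AgreementResult:
    """All agreement statistics for one paired series.

    Statistics that need more pairs than supplied (correlation for
    n < 3, SE-based quantities for n < 2) are reported as NaN rather
    than raising, so single-participant studies still produce a row.
    """
    c, t = _pairs(criterion, test)
    n = len(c)
    crit_mean = float(c.mean()) if n else math.nan
    test_mean = float(t.mean()) if n else math.nan
    try:
        r, p = pearson_r(c, t)
    except ValueError:
        r = p = math.nan
    if n >= 2:
        md, se = mean_difference(c, t)
        bias, lo, hi, _ = bland_altman(c, t)
        ci_l, ci_h = ci_mean(t, level=ci_level)
    else:
        md = se = bias = lo = hi = ci_l = ci_h = math.nan
    try:
        mp = mape(c, t)
    except ValueError:
        mp = math.nan
    if n >= 2 and crit_mean > 0:
        ez_pct, ez_lo, ez_hi = minimum_equivalence_zone(
            crit_mean, ci_l, ci_h, granularity=ez_granularity
        )
    else:
        ez_pct = ez_lo = ez_hi = math.nan
    return AgreementResult(
        n=n, crit_mean=crit_mean, test_mean=test_mean, r=r, r_pvalue=p,
        mean_diff=md, se_diff=se, mape=mp, ba_bias=bias,
        ba_loa_low=lo, ba_loa_high=hi, ci_low=ci_l, ci_high=ci_h,
        ez_pct=ez_pct, ez_low=ez_lo, ez_high=ez_hi,
    )


CLASS_COLUMNS = {"SED": "sed_min", "LPA": "lpa_min", "MVPA": "mvpa_min", "TPA": "tpa_min"}


def agreement_report(
    summaries: pd.DataFrame,
    criterion_device: str,
    test_device: str,
    period: str,
    ci_level: float = 0.90,
    ez_granularity: float = 0.1,
) -> pd.DataFrame:
    """One agreement row per intensity class from a long summary table.

    ``summaries`` must have columns ``participant, device, period`` plus
    the per-class minute columns; participants present for both devices
    in the given period are paired.
    """
    sel = summaries[summaries["period"] == period]
    crit = sel[sel["device"] == criterion_device].set_index("participant")
    test = sel[sel["device"] == test_device].set_index("participant")
    shared = crit.index.intersection(test.index).sort_values()
    if shared.empty:
        raise ValueError(
            f"no participants shared between {criterion_device} and {test_device}"
        )
    rows = []
    for cls, col in CLASS_COLUMNS.items():
        res = compute_agreement(
            crit.loc[shared, col].to_numpy(),
            test.loc[shared, col].to_numpy(),
            ci_level=ci_level,
            ez_granularity=ez_granularity,
        )
        rows.append(
            {"comparison": f"{test_device}_vs_{criterion_device}",
             "period": period, "intensity": cls, **asdict(res)}
        )
    return pd.DataFrame(rows)


def bland_altman_plot(criterion, test, title: str = "", path=None):
    """Bland–Altman scatter with bias and 95% limits of agreement.

    Saves to ``path`` when given (PNG/SVG by extension), else returns
    the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bias, lo, hi, points = bland_altman(criterion, test)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(points["mean"], points["diff"], s=18, color="#1f5fa8", zorder=3)
    ax.axhline(bias, color="k", lw=1)
    for y in (lo, hi):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("Mean of methods (min)")
    ax.set_ylabel("Criterion − test (min)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
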