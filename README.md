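# wristpa

Validation analytics for wrist-worn activity monitors: raw tri-axial
acceleration → ENMO → intensity-classified, non-wear-cleaned daily
summaries; breath-by-breath indirect calorimetry → MET-classified
minutes; and the paired-method agreement statistics used to judge
whether a new wrist sensor measures sedentary behaviour and physical
activity as well as an established criterion.

It is written for physical-activity and mHealth researchers who need to
run (or audit) a device-validation analysis end to end, and it ships a
synthetic-data generator that emulates a complete validation study — a
62-minute simulated free-living activity protocol and multi-day
free-living wear with sleep, off-wrist gaps and Bluetooth dropout — with
known ground truth, so every stage is testable without any recorded data.

## The analysis

**Accelerometry.** Raw samples (25 Hz test device, 100 Hz criterion
device, in g) are autocalibrated from static windows, reduced to the
Euclidean norm minus one, ENMO = max(√(x²+y²+z²) − 1, 0), expressed in
milli-g, averaged per second, and classified per second against the
Hildebrand adult non-dominant-wrist cut-points (sedentary < 44.8 mg ≤
light < 100.6 mg ≤ moderate-to-vigorous; a value at a cut-point takes
the higher class). Seconds collapse into wall-clock-aligned 60-s epochs
with intensity-seconds tallies and validity flags.

**Wear cleaning.** Non-wear is detected with the Choi rule on a
per-minute movement proxy of the criterion device (90-min windows of
zero counts, tolerating ≤ 2-min spikes flanked by ≥ 30 min of zeros on
both sides); sleep comes from the self-report log; minutes where the
test device dropped its Bluetooth link are invalid. One shared mask —
wear ∧ ¬sleep ∧ ¬invalid — applies to every source, so exclusion is
never differential.

**Calorimetry.** Breath-by-breath VO₂ (mL·min⁻¹) is collapsed by
time-weighted sample-and-hold onto 10-s bins, averaged into 60-s epochs,
converted to METs (1 MET = 3.5 mL·kg⁻¹·min⁻¹) and classified (SED ≤ 1.5
< LPA < 3.0 ≤ MPA < 6.0 ≤ VPA; MPA+VPA fold into MVPA for comparisons).

**Agreement.** For each intensity class, per-participant minutes from
the test method are compared with a criterion via Pearson r, mean
difference (criterion − test) ± SE, participant-level mean absolute
percent error, Bland–Altman bias with 95 % limits of agreement
(bias ± 1.96 SD), the t-based 90 % CI of the test-method mean, and the
**minimum equivalence zone**: the smallest percentage band
crit_mean × (1 ± EZ/100), on a 0.1-point grid (ceiling), that contains
that 90 % CI.

## Worked example

Simulate four participants for three free-living days each, process both
devices through the full chain, and compare them:

```python
import pandas as pd, wristpa as w
from wristpa import pipeline

rows = []
for i in range(4):
    plan = w.random_week_plan(seed=500 + i, days=3)
    cfg = w.SimConfig(seed=500 + i)                  # default noise & bias
    test, crit, truth = w.simulate_accel_pair(plan, cfg)
    summary, _ = pipeline.analyze_pair(
        test, crit, w.StudyConfig(),
        sleep_intervals=w.sleep_intervals(plan),
        period="per-day", participant=f"P{i+1:02d}",
    )
    rows.append(summary)

report = pipeline.validate_summaries(pd.concat(rows), w.StudyConfig())
print(report[["intensity", "n", "crit_mean", "r", "mape", "mean_diff", "ez_pct"]])
```

which prints

```
intensity  n  crit_mean  test_mean   r  mape  mean_diff  ci_low  ci_high  ez_pct
      SED  4    793.583    793.583 1.0   0.0        0.0 773.729  813.437     2.6
      LPA  4     93.833     93.833 1.0   0.0        0.0  83.104  104.563    11.5
     MVPA  4     35.167     35.167 1.0   0.0        0.0  21.428   48.906    39.1
      TPA  4    129.000    129.000 1.0   0.0        0.0 111.627  146.373    13.5
```

Both simulated devices observe the same motion, so the devices agree
perfectly pair by pair (r = 1, MAPE = 0, zero mean difference). The
equivalence zones are still non-zero: they measure how wide a band
around the criterion mean must be to swallow the *between-participant*
90 % CI of the test-method mean — e.g. MVPA minutes vary a lot between
these four simulated people, so the zone is 39.1 % even though the
devices are indistinguishable. That separation of pairwise agreement
from group-level equivalence is exactly why validation studies report
both.

The equivalence-zone statistic can also be applied directly to published
summary numbers:

```python
>>> w.minimum_equivalence_zone(crit_mean=237.1, ci_low=198.18, ci_high=275.7)
(16.5, 197.9785, 276.2215)
```

i.e. a 90 % CI of [198.18, 275.7] min/day around a criterion mean of
237.1 min/day needs a ±16.5 % zone.

A command-line workflow over CSV studies mirrors the library:

```bash
wristpa simulate --outdir study --seed 1 --participants 4 --days 3
wristpa process  --indir study --outdir processed
wristpa validate --summaries processed/summaries.csv --outdir report
wristpa report   --summaries processed/summaries.csv --outdir report   # BA plots
```

## Layout

| module | responsibility |
| --- | --- |
| `wristpa.simulate` | protocol & free-living generator, fixture studies, ground truth |
| `wristpa.accelerometry` | calibration, ENMO, per-second classes, 60-s epochs |
| `wristpa.nonwear` | Choi non-wear, movement proxy, shared wear/sleep/valid mask |
| `wristpa.calorimetry` | breath collapsing, MET conversion and classes |
| `wristpa.summaries` | analysis-set merge and per-day / per-session summaries |
| `wristpa.agreement` | r, MAPE, Bland–Altman, CIs, minimum equivalence zone |
| `wristpa.config` / `wristpa.cli` | YAML study configuration and the `wristpa` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
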