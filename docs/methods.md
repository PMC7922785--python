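# Methods

This note records the models, parameter choices and numerical decisions
behind `wristpa`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Accelerometry chain

**Autocalibration.** Non-overlapping 10-s windows whose per-axis sample
SD is below 4 mg are treated as static; their mean vectors should lie on
the unit (1 g) sphere. A per-axis linear model (gain·a + offset) is
fitted by iterated least squares toward the closest sphere points. The
fit runs only when there are ≥ 20 static windows whose means reach
beyond ±0.3 g on every axis (orientation diversity — otherwise gain and
offset are not identifiable and the stream is returned unchanged,
flagged uncalibrated), and only when the mean static-norm error is
≥ 5 mg. The skip rule reflects how sphere-based autocalibration is used
in practice: an in-spec device gains nothing from a refit, and windows
of quiet-but-not-still behaviour (reading, typing) would otherwise bias
the gains low by a few tenths of a percent. The 4 mg stillness threshold
follows from the sensor noise model below (2 mg per-axis RMS): true
stillness produces window SDs near 2 mg while even the quietest
sedentary movement typically exceeds 4 mg on the gravity-dominant axis.
A 2 % single-axis gain error produces ≈ 6.5 mg mean static-norm error,
comfortably above the 5 mg skip threshold, and is recovered to within
0.002 in the test suite.

**ENMO.** Per sample, max(‖a‖ − 1, 0) in milli-g; per-second values are
arithmetic means of sample ENMOs within the wall-clock second (the
epoch-mean convention of the standard raw-processing chains). Seconds
with < 50 % of expected samples are missing. ENMO is invariant to axis
permutation and sign, which the suite property-tests.

**Classification and epochs.** Cut-points default to the adult
non-dominant-wrist values 44.8 / 100.6 mg; they are configuration, never
constants in logic, because referenced thresholds drift between
publications. Bands are half-open with the *upper* class winning at a
threshold (the "≥ cut-point" reading). Sixty-second epochs align to
wall-clock minutes — a requirement for merging devices with different
clocks and rates — and are valid only when no second is missing
(tolerance configurable). Vigorous activity is not separated on the
accelerometer side; comparisons use SED / LPA / MVPA / TPA.

## Non-wear, sleep, valid time

The Choi rule runs on per-minute movement: a maximal run of
zero-or-artifactual minutes ≥ 90 min is non-wear, where a nonzero run of
≤ 2 min is artifactual iff flanked on both sides by ≥ 30 consecutive
zero minutes. Because this pipeline has no proprietary activity counts,
the zero-count series is a proxy: round(per-minute mean ENMO), floored
to zero below 1 mg. The floor is the stationary signal level of the
sensor model: with 2 mg per-axis noise, a motionless device shows a mean
ENMO of σ/√(2π) ≈ 0.8 mg, so stillness maps to zero counts while the
quietest simulated sedentary bout (3 mg) stays nonzero. The
implementation is verified minute-for-minute against an independent
brute-force implementation of the run definition on randomized series.

Wear is detected on the **criterion** device only and the resulting
mask — wear ∧ ¬sleep(log) ∧ ¬invalid — applies to all sources
identically; minutes missing from the test device (Bluetooth dropout)
are invalid for everyone. This mirrors how a shared analysis set
prevents differential exclusion bias between methods.

## Calorimetry chain

Breath values hold from one breath to the next, capped at one 10-s bin
width. The cap resolves a contradiction inherent in uncapped holding:
a vendor-style epoch export must mark silent stretches as missing, but
an unbounded hold would happily bridge any gap with stale VO₂. With
breaths 2–4 s apart the cap never triggers in normal data. Bins get the
duration-weighted mean over their covered portion; a 60-s epoch needs
≥ 3 of its 6 bins and averages the available ones. METs are
VO₂ / (3.5 · mass). The printed MET bands in the intensity literature
(≤ 1.5, 1.6–2.9, 3.0–5.9, ≥ 6.0) leave rounding gaps; classification
here uses continuous half-open bands with breakpoints 1.5 / 3.0 / 6.0 so
every value is classified. That choice is ours — the source convention
is unstated — and is flagged, not asserted, as the original authors'.

## Merging and summaries

Sources inner-join on the 60-s grid restricted to the analysis set; a
minute survives only if every requested source has a valid epoch there.
Accelerometer minutes per class are Σ seconds_in_class / 60; calorimetry
contributes whole classified minutes, with MPA + VPA folded into MVPA.
Free-living summaries are means over included days (min/day), where a
day is included if it has at least `min_valid_day_min` analysis minutes
(default 0, i.e. any valid time; a standard 600-min rule can be imposed
in configuration). Whether to average over wear-days or calendar days is
likewise configuration, since conventions differ between studies.

## Agreement statistics

All statistics operate on per-participant paired values, class by class:
Pearson r (p from the t transform, n − 2 df), mean difference with the
**criterion − test** sign convention, SE = SD/√n, MAPE computed at the
participant level (mean of |c−t|/c; pairs with c = 0 dropped with a
warning), Bland–Altman bias ± 1.96 sample SD, and the two-sided t CI of
the test-method mean (90 % by default). The minimum equivalence zone is
the ceiling, to a 0.1-percentage-point grid, of
100 · max(mean − CI_low, CI_high − mean)/mean, floored at zero; the zone
takes the CI bounds as explicit inputs rather than recomputing them, so
it can be applied to published tables whose CI construction is unknown
(published 90 % CIs are often asymmetric and not reproducible from
printed means and SEs). Minimality — containment holds at the returned
percentage and fails one granule lower — is property-tested on 10⁴
random inputs; ceiling comparisons carry a 10⁻⁹ relative tolerance so
exact-multiple inputs (e.g. a required zone of exactly 17.5 %) are not
bumped a granule by floating-point dust.

Note that pairwise agreement and group equivalence are different axes:
two devices can agree perfectly pair by pair (r = 1, MAPE = 0) while the
minimum equivalence zone stays large, because the zone measures the
between-participant spread of the test-method mean around the criterion
mean.

## Synthetic data

The generator emulates the full study design: a 62-minute protocol
session (12 activities of 5 min — four sedentary, four light, four
moderate-to-vigorous — separated by two 1-min transits) and multi-day
free-living wear, recorded by a 25 Hz test device and a 100 Hz criterion
device worn together, with paired breath data and sleep / non-wear logs.

**Acceleration model.** Within a bout the signal is a constant gravity
unit vector scaled by 1 + m(t), m(t) = (e/1000)(1 − cos 2πft), with e
the bout's target ENMO in milli-g and f ∈ {1, 2, 3} Hz. Because f is an
integer, every wall-clock second contains whole oscillation cycles at
both 25 and 100 Hz, so the per-second mean ENMO of the noise-free signal
equals e *exactly* — ground truth is analytic, not empirical. White
per-axis noise (default SD 2 mg, the RMS noise of a modern MEMS wrist
sensor at these bandwidths) and a small residual z-offset on the test
device (default 5 mg) are added on top; orientation is piecewise
constant per bout rather than continuously drifting.

**Protocol targets.** Per-activity ENMO/MET targets sit comfortably
inside their class bands (sedentary 4–12 mg / 1.0–1.4 MET, transits
20 mg / 1.4 MET, light 60–85 mg / 1.8–2.5 MET, MVPA 180–400 mg /
3.5–8.0 MET), since the source protocol prints activity names but no
per-activity accelerations. Transits classify as sedentary by their
targets, so the noise-free session yields 22/20/20 SED/LPA/MVPA minutes.

**Free-living plans.** Days run 07:00–23:00 awake by default; waking
windows are tiled with bouts drawn per participant (sedentary 60 % of
draws at 20–50 min, light 25 % at 5–15 min, MVPA 15 % at 3–10 min,
targets drawn inside the class bands), giving the sedentary-heavy
profile typical of wrist-based free-living estimates. Some days carry a
100–150-min off-wrist gap (device still, on a surface); the test device
additionally suffers 10–30-min dropout gaps (samples absent). All events
are minute-aligned; overlapping gaps are rejected. Mean wear time is a
parameter of the plan generator rather than a fixed constant, since
observed wear in field studies varies widely.

**Breaths.** Breath intervals are jittered uniformly in 2–4 s; VO₂
fluctuates with CV 8 % around target_met · 3.5 · mass, with first-order
onset kinetics (τ = 30 s) at block transitions and the session starting
at the first block's steady state.

**What the simulations show — and don't.** Noise-free recovery is exact
by construction, and recovery under default noise is exact in practice
because class targets sit ≥ 5 mg from every cut-point while per-second
noise on the ENMO mean is ≈ 0.4 mg; the suite's 5 % recovery bound is
therefore extremely conservative. Real wrist data violate the model in
ways the generator deliberately omits: ENMO values crowd the cut-points
(so classification error is far larger), orientation changes within
bouts, non-wear is not perfectly still, sleep logs are imprecise, and
device clocks drift. Passing recovery tests demonstrates the *pipeline*
is correct, not that the devices (or the cut-points) are accurate in the
field.

## Problem sizes

The test suite exercises the full chain on short plans (one to two days,
2–4 h waking windows) and runs the complete 7-day single-participant
recovery — noise-free and default-noise — in the acceptance tests;
full-rate, full-week CSV fixtures are gigabyte-scale, so on-disk fixture
studies in the tests use the short plans while in-memory analyses run at
full scale through the identical code path.

## Known limitations

- No activity-count emulation; the Choi proxy uses ENMO with a
  documented floor, and whether the original count series was
  vector-magnitude or single-axis is configuration (`movement_proxy` is
  the single switch point).
- No gyroscope, PPG/heart-rate, GPS, step counting, or bout-level
  metrics; no algorithmic sleep detection (logs only).
- Calibration fits gain/offset only (no temperature term, no full
  ellipsoid).
- The equivalence-zone statistic reports containment, not TOST p-values.
- Timestamps are timezone-naive local time at millisecond resolution
  (single-site assumption; DST is out of scope).
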