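# Methods

This note records the models, conventions and design choices behind
`cgmetrics`, in the order data flows through the pipeline.

## Trace handling

A glucose trace is a timezone-naive timestamped series in mg/dL,
validated against the sensor reporting range [40, 500]. Day boundaries
are local midnight; study day 1 is the calendar day of sensor
activation. Because a windowed trace cannot infer a missing day 1 from
its own samples, the activation date is carried on the trace object
(`GlucoseTrace.activation_date`) and may be supplied explicitly when
reading external data.

Resampling places every trace on a regular grid (default 15 min,
matching the historic-record cadence of flash CGM sensors) anchored at
midnight of the first sample's day. Interpolation is linear only — no
smoothing, because excursion-based indices such as MAGE are sensitive
to filtering. A grid point is emitted as missing whenever its
bracketing observations are not both within `max_gap` (default 60 min);
interpolation therefore never bridges long sensor dropouts, and nothing
is extrapolated beyond the observed extent.

The analysis window keeps study days 2–14: the first 24 h of sensor
output is discarded (sensor equilibration), and nothing beyond two
weeks is used. A calendar day contributes to summaries only if at least
70 % of its grid points are present — a conventional completeness
threshold for per-day CGM metrics; days below it are flagged rather
than dropped silently, and cross-day aggregates skip them.

## Index conventions

Published implementations of several GV indices disagree in small ways;
the choices fixed here are:

* **Sample SD** (`ddof=1`) everywhere, including CONGA.
* **Reading-based percentages** for TIR/rTIR/TAR/TBR, valid because
  traces are gridded first; boundaries closed ([70, 180] and [70, 110]
  inclusive), TAR strictly > 180, TBR strictly < 70. The three
  fractions partition 100 % exactly on every day with data.
* **MAGE**: turning-point method. Interior local extrema are located on
  the unsmoothed day profile (plateaus collapse into single extrema);
  swing amplitudes are measured between consecutive turning points,
  including the leading and trailing segments to the day's endpoints;
  amplitudes strictly greater than the day's SD qualify; up- and
  down-excursions are averaged together. A monotone or constant day
  scores 0. No sub-threshold merging of adjacent excursions is
  performed — the amplitude sequence is taken as scanned; this is the
  simplest member of the MAGE family and is mirrored exactly by the
  brute-force oracle the tests use.
* **Risk transform**: the standard mg/dL parameterization
  f(g) = 1.509·[(ln g)^1.084 − 5.381], risk 10·f², split into low/high
  branches at the root (~112.5 mg/dL). LBGI/HBGI are per-day means of
  the branch risks; ADRR averages daily (max low + max high) over valid
  days. Constants live in one frozen dataclass.
* **MODD** uses matched clock times on consecutive valid days only, and
  skips pairs with a missing member. **CONGA** defaults to a 1-h lag
  (configurable); pairs spanning missing points are skipped and at
  least two lagged differences are required.
* Degenerate inputs (empty or single-reading days, no aligned day
  pairs) return NaN markers, never exceptions, so batch tables always
  build.

## Metabolic-score surrogate

Commercial daily metabolic scores are proprietary; `cgmetrics` defines
an explicit composite from the same three ingredient families so its
behavior is analyzable. Subscores on 0–100: rTIR itself (the tight
70–110 band is used, matching preventive-wellness practice, rather than
the diabetes-management 70–180 band); a mean-glucose ramp maximal on
[70, 110] falling linearly to 0 at anchors 40 and 250 mg/dL; and
100·(1 − min(CV/36 %, 1)), 36 % being the consensus glycemic-stability
threshold. Default weights 0.40/0.35/0.25 (GV/rTIR/mean) sum to 1 and
are configuration, not code. Whether within-day or rolling-window GV is
the right ingredient is unknowable for proprietary scores; this
surrogate uses within-day CV and claims no numerical agreement with any
app-displayed value. The score is monotone by construction:
non-increasing in CV and in the mean's distance from the target band,
non-decreasing in rTIR.

## Synthetic cohorts

The generator emulates the study conditions the package is benchmarked
against: 53 healthy and 52 pre-diabetic adults, 14 days at 15-minute
sampling. Per subject, glucose is

    baseline(day) + circadian + Σ meal pulses + AR(1) noise,

clipped to [40, 500].

* **Latent dysglycemia factor** z ~ N(0,1), drawn once per subject,
  shifts baseline (weight 0.6 of the between-subject SD), scales meal
  amplitudes multiplicatively, and loads on the biomarker panel. This
  single factor is what produces the within-cohort correlation between
  realized GV (J-index, HBGI) and HOMA-IR/OGTT/HbA1c/Hs-CRP; the
  pre-diabetic loading (0.5) yields r ≈ 0.4–0.55, the healthy loading
  (0.15) keeps correlations weak.
* **Circadian** cosine (amplitude 9–9.5 mg/dL, peak 16:00, nocturnal
  trough ~04:00).
* **Meals** at 08:00/13:00/20:00 ± 25 min, lognormal amplitudes
  (healthy median 36 mg/dL, σ = 0.35; pre-diabetic median 35,
  σ = 0.55 — a fatter tail with slower decay produces the pre-diabetic
  hyperglycemic dwell time), linear rise then exponential decay.
* **AR(1) noise** at the 15-min step, ρ = 0.8, stationary SD
  8.5–10.5 mg/dL — CGM error and short-scale physiology are strongly
  autocorrelated.
* **Across-day drift**: baseline and meal amplitude decline linearly
  (−0.45/−0.6 mg/dL·day and ~−1 %/day), anchored at the mid-window day
  so the drift expresses improvement over time without moving the
  days 2–14 average.

Biomarkers are drawn per cohort with the z-loading and clipped into the
ADA screening bands that define cohort eligibility (healthy: FBG 79–99
mg/dL, HbA1c 4.0–5.6 %, OGTT < 140 mg/dL; pre-diabetic: 100–125,
5.7–6.4, 140–199). End-of-study fasting glucose applies a convergent
shift (+1.8 healthy, −2.8 pre-diabetic mg/dL). HOMA-IR is derived as
glucose·insulin/405 from a simulated lognormal fasting insulin, since
insulin itself is an internal quantity. Hs-CRP uses a 2× cohort ratio
(medians 1.2 vs 2.4 mg/L). Activity (steps, heart rate, sleep) has
subject- and day-level noise with weak z-couplings (less activity and
sleep, higher heart rate with higher dysglycemia).

**Calibration.** All archetype constants live in
`presets/default.yaml`, not in code. They were tuned once, by iterative
simulation, so the full pipeline's days 2–14 cohort summaries match the
benchmark values quoted in that file (mean glucose 102.4/112.2 mg/dL,
GV-SD 16.2/19.4, GV-CV 15.8/17.3 %, TIR 95.3/94.6 %, TAR 0.1/1.4 %,
MAGE 30.7/32.9). One published inconsistency is worth noting: the
benchmark's healthy TIR/TAR/TBR (95.3/0.1/1.6 %) cannot sum to 100 as a
partition. The presets therefore prioritize the partition-consistent
quantities (TIR and TAR); the implied healthy TBR settles between the
printed value and the partition complement.

**What the generator does not emulate**: real meal logs or behavioral
change, sensor-specific error spectra, compression artifacts, dropout
patterns beyond random gaps, skewed activity distributions, and any
feedback from app nudges onto glucose. Passing calibration therefore
shows that the analysis stack recovers known cohort structure from
realistic-looking traces — not that the generator is a physiological
model of any individual.

## Statistics

* **Outliers**: one pass only; mean ± 3 SD for normal vectors,
  Q1 − 3·IQR / Q3 + 3·IQR with type-7 (linear interpolation) quantiles
  otherwise. Stated explicitly because the 3×IQR rule depends on the
  quantile definition.
* **Correlation**: Shapiro-Wilk at α = 0.05 per variable gates Pearson
  (both pass) vs Spearman; two-sided p; ≥ 5 complete pairs; zero
  variance yields an undefined marker. No multiplicity correction by
  default, matching the tabular presentation style the pipeline mirrors;
  `correlation_grid(..., adjust=True)` applies Benjamini–Hochberg.
* **Cohort × day**: ordinary least squares with cohort, categorical
  day, and their interaction; type-II p-values; least-squares means are
  the cell means (the model is saturated) with CIs from the pooled
  residual variance. Subject-days enter as complete cases; no
  repeated-measures correlation structure is modeled — a deliberate
  simplification (no mixed-effects modeling is in scope), documented
  rather than hidden.
* **ANCOVA**: end ~ cohort + baseline, with a plain two-group fallback
  (and warning) when the baseline is constant.
* **ROC**: empirical curve and AUC; orientation is fixed toward the
  positive cohort's mean so a protective index (lower in pre-diabetics)
  is negated first. AUC equals the Mann–Whitney U statistic rescaled by
  n₁·n₂, which the tests assert as an identity.

## Problem sizes and determinism

All randomness flows from `numpy.random.SeedSequence`; identical
(config, seed) reproduce byte-identical CSVs. Test fixtures use reduced
studies (≤ 20 subjects per cohort, ≤ 6 days); calibration-recovery
checks and the acceptance script use the full 53 + 52 × 14-day design,
averaged over ten simulation replicates, which runs in well under a
minute per cohort batch. Statistical null-calibration tests
(type-I error of the two-factor comparison in [3 %, 7 %] at 200
replicates, CI coverage, permutation uniformity) run on fixed generator
streams; the underlying p-value uniformity was verified once at 1500
replicates.

## Known limitations

* Reading-based (not duration-weighted) range percentages; equivalent
  on a complete grid, slightly different under missingness.
* The MAGE variant is one member of a family; values can differ by a
  few mg/dL from smoothing-based implementations on noisy data.
* The two-factor endpoint comparison treats subject-days as
  exchangeable within cells; with strong within-subject correlation its
  p-values are anti-conservative. Interpret them as descriptive, as the
  per-day LSM/CI table is the primary output.
* The metabolic-score surrogate is a documented stand-in for
  proprietary scores and should not be compared numerically to any
  product's display.
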