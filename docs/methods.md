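# Methods

This note documents the models behind `perimsim`: what is simulated, with
which parameters and units, which numerical conventions the analysis
uses, and what the simulation deliberately does not try to reproduce.

## 1. Grid and zones

The 30-2 pattern is the set of lattice points (x, y) with
x, y ∈ {±3, ±9, ±15, ±21, ±27} degrees and eccentricity
√(x² + y²) ≤ 28.5° — 76 points. Coordinates follow the right-eye
convention (x > 0 temporal, y > 0 superior); left-eye fields are stored
as recorded and mirrored (x → −x) when they enter analysis. The two
points adjacent to the physiological blind spot, (15, ±3), are excluded
from all statistics, leaving 74 analysable locations.

Zones partition the analysable points by eccentricity rounded to one
decimal:

| zone   | eccentricity (deg) | points |
|--------|--------------------|--------|
| inner  | 4.2 – 17.5         | 30     |
| middle | 21.2 – 22.8        | 20     |
| outer  | 25.8 – 28.5        | 24     |

The canonical location order is row-major, y descending (superior first),
x descending within a row. Because the lattice is closed under x → −x and
y → −y, mirroring loses no locations.

## 2. Normative analysis

Given a normative model (per-location age-expected sensitivity, decade
slope, SD, and empirical deviation cutoffs):

* **Total deviation (TD)** = measured − age-expected, with the
  age-expected value computed at the patient's age via the per-location
  decade slope. Ages outside the model's calibration range are clamped
  with a warning.
* **General height (GH)** = the 11th highest of the 74 TD values (the
  fixed-rank ~85th percentile), an estimate of diffuse loss that is robust
  to focal defects.
* **Pattern deviation (PD)** = TD − GH.
* **Probability maps** assign each location a category NS / p<5% / p<2% /
  p<1% / p<0.5% by comparing TD (or PD) with the per-location empirical
  percentile cutoffs; a value exactly on a cutoff takes the rarer
  category. Categories are ordered integers so "at least p<1%" is a
  simple comparison; excluded locations carry −1.
* **Global indices**: MS is the unweighted mean sensitivity; MD is the
  variance-weighted (1/SD²) mean of TD; PSD is the weighted SD of TD about
  MD. With equal weights these reduce to the plain mean and SD.
* **Grey-scale rendering**: linear interpolation of sensitivity onto a
  raster over ±30°, nearest-neighbour fill outside the tested hull, 0 dB
  black to 40 dB white. Interpolated values are rounded to 10⁻⁶ dB before
  quantisation so grey levels on an exact rounding boundary resolve
  identically at every pixel.

## 3. Agreement metrics

* **Zonal RMSE** between two exams of the same eye, over the whole field
  or one zone. The whole-field RMSE² is by construction the
  24/20/30-weighted mean of the zonal RMSE²s (tested to 1e-12). Group
  summaries average per-patient RMSEs and give a normal-approximation
  (default) or t-based 95% CI.
* **Dissimilarity** between two probability maps: the percentage of the 74
  locations where one map calls the location defective (at or beyond a
  chosen category, default p<5%) and the other does not. Depth
  differences between two defective calls do not count.
* **Depth aggregate**: the sum of category codes over the field (0–296),
  a crude severity score monotone in every location's category.
* **Reliability filter**: false positives < 33%, false negatives ≤ 33%,
  fixation losses ≤ 20%; returns the failure reasons.
* **Severity classification**: an ordered rule table over deep defects
  (default: category ≥ p<1% on the TD map). First matching rule wins:
  Severe if all three zones are involved or ≥ 20 deep defects; Moderate
  if ≥ 2 deep defects in both outer and middle zones; Mild if ≥ 2 deep
  defects anywhere; otherwise Nil. A single flagged location is treated
  as noise. Rule tables are user-replaceable (JSON/YAML) and validated.
* **Diagnostic rates**: against a gold-standard labelling, the FP rate is
  the fraction of gold-normal patients labelled defective, the FN rate
  the fraction of gold-defective patients labelled normal. Empty
  denominators yield `None`, never a fake 0.
* **Cohort summary**: per-algorithm/visit means and SDs of MS/MD/PSD,
  mean durations in minutes (1 dp), visit-3 MS differences vs Full
  Threshold (2 dp), and the visit-3 MD pooled across algorithms (2 dp).

## 4. Simulation model

All randomness flows from one root seed through named
`numpy.random.SeedSequence` spawns; no global state.

### Normal population

Sensitivity at eccentricity e for age a (years):

    S(e, a) = 34.0 − 0.28·e − (0.55 + 0.010·e)·(a − 45)/10   [dB]

plus a per-subject general-height offset N(0, 1.0 dB) and independent
per-location deviations N(0, (0.6 + 0.05·e) dB).

### Vigabatrin loss pattern

A sigmoid in eccentricity, scaled by severity s ∈ [0, 1] and amplified
nasally:

    loss(e) = 20·s · σ((e − 19)/4) · (1.5 if x < 0 else 1)   [dB]

This gives relative central sparing (a few tenths of a dB near fixation),
a steep transition through the middle zone, and saturating peripheral
loss — concentric constriction with nasal predominance. Thresholds floor
at 0 dB.

### Observer

Seen/not-seen responses follow a frequency-of-seeing curve

    p(seen) = fp + (1 − fp − fn)·Φ((threshold − stimulus)/σ)

with fp = fn = 0.03 and slope σ = 1.2·(1 + 0.05·e + 0.04·max(loss, 0)) dB:
flatter psychometric functions in the damaged periphery, the main driver
of eccentricity-graded test-retest variability. Between visits the true
thresholds are jittered by N(0, 0.8·(1 + 0.06·e) dB).

### Strategies

* **Full Threshold**: 4-2 dB staircase. Step 4 dB until the first
  response reversal, then 2 dB until the second; estimate = last seen
  level; levels clamp to [0, 40] with double-confirmation termination at
  the edges. Against a deterministic observer the estimate error is 0 or
  −1 dB depending on parity (mean ≈ −0.5 dB) — the staircase's intrinsic
  bias.
* **SITA surrogate**: ZEST on the discrete 0–40 dB domain. The prior is
  bimodal — a normal mode centred on the age-expected value (SD 3.5 dB,
  weight 0.75) plus a broad abnormal mode N(4, 8) — updated with a
  cumulative-Gaussian likelihood (slope 1.5 dB, lapse 0.03); each stimulus
  is placed at the posterior mean; the run stops when the posterior SD
  falls below the tolerance (Standard 2.0 dB, cap 6 presentations; Fast
  3.0 dB, cap 5); estimate = posterior mean. This is *not* the
  proprietary SITA machinery. It reproduces the two structural properties
  the downstream comparisons need — fewer presentations than the
  staircase (with Fast below Standard) and slightly higher, more
  prior-anchored estimates — but its duration advantage over Full
  Threshold is smaller than the real SITA's (about 0.85× and 0.7× here
  versus roughly 0.5× and 0.3× clinically), because the real timing gains
  also come from inter-stimulus pacing adaptations that a
  presentation-count model cannot capture.

Exam duration = (threshold presentations + 3×15 catch trials) × 2.0 s.
Catch-trial FP/FN/fixation-loss percentages are binomial draws from the
patient's response error rates.

### Normative database calibration

The normative model is fitted to *measured* simulated exams, not to the
noise-free population: each of the (default 300) normal subjects' true
fields is measured with the 4-2 staircase before the per-location age
regression, residual SDs and percentile cutoffs are computed. This
mirrors how clinical normative databases are built and is essential for
calibration — cutoffs from noise-free fields are far too tight once
estimation error is added, and flag several times the nominal fraction
of normal locations. For the same reason the clinical-exam simulator
uses the *same staircase start policy* as the calibration exams
(rounded population age-normal values): 4-2 estimates live on a discrete
lattice anchored at the start value, and a 1 dB start offset shifts the
estimate distribution against the percentile cutoffs and roughly doubles
the p<5% tail. A `measured=False` variant fits the noise-free population
for methodological comparisons.

With n = 300 subjects the extreme cutoffs (p<0.5%) rest on ~1.5 expected
tail observations per location, so their sampling error is visible; the
acceptance checks therefore test the p<5% and p<1% rates with bands
([3, 7]% and [0.5, 2.5]%) that allow for percentile estimation error and
the 2 dB quantisation granularity of staircase estimates, whose flag
rates cannot move continuously.

### Cohorts

`simulate_cohort` draws n patients (default 16; ages N(39.3, 14.5)
clamped to the model's calibration range), assigns a fraction
(default 6/16) vigabatrin-pattern loss with severity U(0.3, 1.0), and
examines each with all three strategies at two visits. Test order
follows four counterbalanced protocols (A–D) assigned round-robin after
a seeded shuffle, balancing fatigue across strategies.

## 5. Reference tables

`perimsim/data/` bundles two small CSVs describing a 16-patient
three-strategy study: per-patient severity labels under each algorithm,
and group-level means/SDs of MS, MD, PSD and duration per algorithm and
visit. They act as exact, human-checkable vectors for the agreement
arithmetic (FP 10% for both fast strategies on 10 gold-normal patients,
FN 0% and 17% on 6 gold-defective patients, 38% prevalence, durations
15.8/7.6/4.7 min, visit-3 MS deltas +1.25/+1.51 dB, pooled visit-3 MD
−4.76 dB). They are data, not code: nothing in the simulation is fitted
to them.

## 6. Limitations

* The SITA surrogate shares the real strategies' structure, not their
  implementation; absolute durations and the size of the speed advantage
  are not clinically calibrated (see above).
* One global per-presentation time (2.0 s) converts presentation counts
  to durations; real inter-stimulus timing is adaptive.
* The loss model is a smooth radial sigmoid; it does not simulate
  hemianopic, arcuate or scotomatous patterns, media opacity, or lens rim
  artefacts.
* Normative percentile cutoffs use the empirical per-location percentile
  at the default n = 300; rarer categories are correspondingly noisy.
* Severity rules are a deliberately simple zone-count table, intended to
  be replaced by study-specific tables via `load_severity_rules`.
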