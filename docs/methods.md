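# Methods

This note documents the statistical model behind `snapscreen`, the design
choices that were genuinely open, the synthetic-data generator's assumptions,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Assay model

A structure-comparison ELISA screen measures chemiluminescence for a library
of tagged proteins incubated against two immobilized nucleic-acid structures
(reference, e.g. DNA duplex; test, e.g. triplex), in biological replicates,
on multi-well plates. The analysis assumes:

1. **Multiplicative signal.** Luminescence errors are multiplicative, so all
   analysis happens on the log2 scale. Non-positive RLUs are rejected
   upstream rather than floored: log2 is undefined there and silent flooring
   would distort z-scores.
2. **Plate effects are shared.** Reader gain, coating efficiency and
   substrate batch shift all wells of a plate by a common log2 offset.
   Standardizing each well against the *same plate's* empty background wells
   (mean μ_bg, sample SD σ_bg over empty-well log2 RLU) cancels the offset
   exactly. Backgrounds are never pooled across plates or conditions.
3. **Empty wells estimate the null.** Wells with no tagged protein carry the
   same well-to-well noise as factor wells minus any binding signal, so
   their log2 spread estimates the null SD. Negative-control (GFP) wells are
   *not* background — they contain lysate and are tracked separately as
   controls.

### z-scores, Δz, classification

Per well, `z = (log2 RLU − μ_bg)/σ_bg`. Replicate z-scores are averaged per
factor and condition before thresholding (per-replicate values are retained
for QC); Δz is the test-minus-reference difference of those means.
Classification uses fixed, inclusive thresholds: recruited iff
max(z_a, z_b) ≥ z_cut (default 5); among recruited, test-selective iff
Δz ≥ dz_cut (default 2.5), reference-selective iff Δz ≤ −dz_cut, else
nonselective. The four classes partition the library by construction. No
per-factor p-values or multiple-testing corrections enter hit calling — the
procedure is a fixed-threshold rule, and the classes are reported alongside
raw statistics so a user can re-threshold.

log2 fold change is the difference of mean log2 luminescence (test −
reference). It is a reporting and sorting quantity only (waterfall
tie-break); when the two conditions sit on different plates, plate offsets
leak into it, whereas z and Δz are immune. This is documented rather than
"fixed" because fold change plays no role in classification.

### Replicate QC

Reproducibility is scored by OLS regression of replicate-2 z on replicate-1
z across factors (both conditions pooled by default; subsets by condition or
classification supported). R² equals the squared Pearson correlation, and
the p-value tests the zero-slope null two-sidedly. The regression direction
affects only slope/intercept, never R².

### Category enrichment

Hit frequency per annotation category (DNA repair / chromatin-associated /
other control) is compared with an exact one-sided hypergeometric test in
the observed direction: for a category of size n in a library of N with K
total hits, the expectation is nK/N; k ≤ expected is tested with the lower
tail P(X ≤ k), k > expected with the upper tail (a tie reports "depleted" by
convention, with p ≥ 0.5). Tails are computed by exact integer summation of
binomial coefficients (`math.comb`), not a normal approximation, so they
agree with subset enumeration to the last bit; `scipy.stats.hypergeom` is
used in the test suite as an independent cross-check only. Three hit
definitions are exposed (recruited in either structure; test-selective;
reference-selective). No multiple-testing correction is applied across the
three categories; outputs carry all p-values so a user can adjust.

### ChIP-qPCR percent input

With input fraction f (default 2%) and amplification efficiency E (default
2.0, perfect doubling; exposed as a parameter),

    adjusted input Ct = Ct_input − log_E(1/f)
    percent input     = 100 · E^(adjusted input Ct − IP Ct)
    fold enrichment   = percent input / mean(reference-group percent inputs)

Technical replicates are averaged on the Ct scale before exponentiation.
Per-run Ct offsets cancel (shift invariance), and fold enrichment of a
lone reference sample is 1 by construction. No ΔΔCt-vs-reference-gene mode
and no standard-curve quantification are provided.

## Synthetic-data generator

The generator emulates the screen the analysis is built for:

    RLU = 2^(μ + plate_effect + effect(factor, condition) + ε),
    plate_effect ~ N(0, plate_effect_sd),  ε ~ N(0, well_noise_sd),
    empty wells: effect = 0.

Defaults: μ = 14 (background ≈ 16 000 RLU), plate_effect_sd = 0.5,
well_noise_sd = 0.25 log2 units, 384-well plates with 64 empty wells each,
biological duplicates, one plate set per (condition, replicate) — the
parallel-plates-per-structure layout of the original assay. Dedicated
controls (GFP negative; XPA and RPA2 positive, triplex-recruited) appear on
every plate. Because noise is Normal on the log2 scale, null factor-well
z-scores are standard normal up to background-estimation error — the
property that makes every downstream statistic testable against closed
forms.

`paper_scale_config()` reproduces the published screen's composition: 520
factors (336 DNA repair, 64 chromatin-associated, 120 other controls) with
126 planted binders — 16 triplex-selective, 17 duplex-selective, 93
nonselective — placed so the non-chromatin control category carries a 12.5%
hit rate (15/120) against 24.2% overall. True effects (z-units): selective
binders (1, 9) / (9, 1), nonselective (8, 8), chosen a priori so that, with
64 empty wells per plate, null and selective factors clear every decision
threshold by more than 4 combined-noise SDs (see below).

### Noise accounting and classification margins

A measured z-score is `(effect + ε − δμ)/σ̂` with δμ the background-mean
error and σ̂ the estimated background SD, so for a factor with true z-score
t the replicate-mean z has variance (delta method)

    var(z̄) ≈ [1 + 1/n_empty + t²/(2(n_empty − 1))] / R

for R replicates: unit well noise, mean-estimation noise, and a
*multiplicative* term from σ̂ that grows with the true signal. The truth
table records, per factor, the distance from its true statistics to the
nearest decision threshold in these combined-noise SDs (`margin_sd`). Two
consequences matter:

* **Nonselective binders can never be margin-safe.** Their true Δz is 0,
  only 2.5 away from either cutoff, while sd(Δz̄) ≥ 1 z-unit for duplicate
  screens (two independent unit-noise wells per condition, halved by
  replicate averaging, doubled by differencing). Each nonselective binder
  therefore strays past ±2.5 with a few-percent probability regardless of
  effect size, and recovered selective counts scatter by a couple of
  factors around the planted 16/17/93. Tests assert recovery within
  statistically safe bounds and exact agreement only for factors whose
  margin exceeds 4 SDs.
* **Strong hits are noisier than weak ones in z units** (the t² term), which
  is why planted effects sit at 8–9 rather than, say, 20 z-units: larger
  effects would *reduce* classification stability at a fixed empty-well
  count.

### Replicate-correlation calibration

With a shared per-factor-per-condition effect of SD s (in z-units, constant
across replicates) and per-replicate noise variance
v = 1 + 1/n_empty + s²/(2(n_empty − 1)) (averaging the multiplicative term
over factors), the correlation between replicate z-scores is

    r = s² / (s² + v),    and the regression R² = r².

`reproducibility_config(target_r_squared=…)` inverts this relation for s, so
a requested R² of 0.92 — the reproducibility regime of a well-behaved
screen — requires r = √0.92 ≈ 0.959, i.e. a shared-effect SD of ≈5.4
z-units. Note R² is the *square* of the shared-variance fraction, not the
fraction itself; conflating the two would miscalibrate the generator by
several points of R². The planted-hit configuration is calibrated to the
partition, not to R²: its whole-screen R² is lower (most factors are null)
and rises in the selective subset, the pattern real structure screens show.

### What the generator does not model

Per-factor lysate expression variability (a real screen's main source of
false negatives), spatial row/column/edge effects (the analysis applies no
spatial correction either), antibody saturation, and heteroskedastic
detector noise. Passing tests therefore demonstrate correctness of the
*analysis* under its own noise model, not robustness of the assay to these
artifacts.

## Numerical conventions and degenerate inputs

* Background SD uses the sample (n−1) convention; with small empty-well
  counts this is the conservative choice. Fewer than 2 empty wells, or
  identical empty wells (σ̂ = 0), is a hard error; fewer than 8 logs a
  warning. The generator's 64 empties/plate keep σ̂ noise small.
* Well addresses are row letter + unpadded 1-based column ("A1".."P24");
  zero-padded input is rejected to avoid silent "A01"/"A1" duplicates.
* Thresholds are inclusive (≥); z_cut = 0 with dz_cut = 0 is permitted and
  degenerates to "everything recruited, Δz ties test-selective".
* Waterfall sorting is stable (mergesort) with log2 fold change as the
  documented tie-break.
* Exact hypergeometric tails are integer ratios converted to float once;
  p-values are reported unrounded.
* All simulation randomness flows from a single `numpy` generator seeded by
  `config.seed`; identical seeds give byte-identical output files.

## Problem sizes

The test suite simulates the 520-factor screen (≈2 700 wells on 8 plates)
hundreds of times — 100 planted and 100 null replicates in the recovery
suite — which completes in well under a minute on one CPU; the enumeration
oracle for the hypergeometric test covers every parameter combination up to
a universe of 12. These sizes were chosen as the smallest that exercise the
asymptotics the tests assert (KS normality at n > 2000, R² convergence at
520 factors, ≥99% margin-safe agreement).

## Known limitations

* Whether the original analysis averaged background SDs across plates or
  used per-plate SDs is ambiguous in its description; per-plate is
  implemented (it is the variant that cancels plate effects exactly). A
  pooled variant would tighten σ̂ at the cost of sensitivity to plate
  heteroskedasticity.
* Fold change on raw log2 means (not background-corrected) is kept for
  fidelity to the assay's reporting; users comparing across plates should
  rank by Δz.
* Control pass/fail for positive controls requires an expected-condition
  map for strict checking; without one, recruitment in either condition
  passes.
* The hit-calling rule is a fixed threshold, so its false-discovery
  behaviour depends entirely on the noise scale; the null-screen simulation
  (0 recruited at 520 factors, z_cut = 5) quantifies it under the model
  only.
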