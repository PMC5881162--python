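# Methods

## Problem

Efavirenz exposure after an oral dose is governed mainly by CYP2B6 activity.
The three 516 G>T genotype classes behave as extensive (EM), intermediate
(IM) and poor (PM) metabolizer phenotypes with decreasing apparent oral
clearance. The package asks: after a single 600 mg test dose, how well does
**one** plasma concentration, drawn at the best of {2, 4, 8, 12, 24} h,
identify a PM? The answer is produced by simulation: a calibrated virtual
population generates concentration–phenotype pairs, an empirical Bayes
classifier is trained on them, and classification performance across
sampling times selects the optimal time.

## Population PK surrogate

**Structural model.** One-compartment disposition with first-order
absorption:

    C(t) = F·D·ka / (V·(ka − k)) · (e^{−k·t} − e^{−ka·t}),    k = CL/V,

with dose D = 600 mg, concentrations in ng/mL (mg/L × 1000). The original
cohorts were produced by a proprietary whole-body PBPK simulator with a
compartmental absorption transit model; only the *marginal* concentration
distributions at the candidate sampling times enter the classifier, so the
surrogate is designed to match population summary statistics, not mechanism.
The degenerate flip-flop case ka = k is excluded by resampling (tolerance
1e−6 on |CL/V − ka|).

**Between-subject variability.** CL/F, V/F and ka are independent lognormals
per subject. Defaults: cv_v = 0.25, cv_ka = 0.30, mean ka = 0.6 /h — typical
oral-absorption values; both CVs and ka are configurable.

**Calibration.** Per phenotype the targets are the published predicted
population means (single 600 mg dose):

| phenotype | CL/F (L/h) | AUC(0−∞) (µg·h/mL) | Cmax (ng/mL) |
|-----------|-----------|--------------------|--------------|
| EM        | 12.8      | 66.8               | 1850         |
| IM        | 6.9       | 108.4              | 1952         |
| PM        | 4.7       | 153.2               | 2135         |

(The published AUC column is headed "ng/L.h"; dimensional analysis with a
600 mg dose and CL in L/h forces µg·h/mL ≡ mg·h/L, and that reading is used
throughout.) The printed mean AUC and mean CL are individually inconsistent
with AUC = D/CL; under a lognormal clearance they are reconciled exactly by
the moment identity E[1/CL] = (1 + CV²)/E[CL], giving

    cv_cl = sqrt(mean_auc · mean_cl / D − 1)

(EM 0.652, IM 0.497, PM 0.447). If the targets make the radicand negative,
calibration aborts with an error naming the phenotype. The mean volume is
then adjusted so the *population mean* Cmax (closed-form per-subject peak,
averaged by 24-node Gauss–Hermite product quadrature over the three
lognormals — deterministic and smooth) hits the Cmax target via Brent root
finding on mean_v ∈ [50, 1500] L; ka stays fixed because a single Cmax
target cannot identify V and ka jointly. Calibrated volumes come out near
265–282 L.

**Randomness.** One master seed. Each (stage, cohort flavour, trial) gets an
independent child stream via `SeedSequence(seed, spawn_key=(stage_offset +
flavour, trial))`, so growing the trial count, or simulating training,
verification and blinded cohorts in any order, never reshuffles existing
draws. Sex is recorded as metadata to mirror the 50%-female designs but has
no effect on the model (no sex effect was reported to implement).

**Non-compartmental summary.** Per subject on the 0–72 h, 0.5 h grid:
trapezoidal AUC(0–72) plus terminal extrapolation C_last/λz, with λz from a
log-linear fit over the last 8 grid points (68.5–72 h, where absorption has
fully decayed, so λz equals k exactly in this model); Cmax is the grid
maximum; CL = D/AUC. Population mean is over subjects; the reported interval
is the 2.5–97.5 percentile range of per-trial means (the published interval
definition is unstated; this choice is flagged). Predicted:observed ratios
are reported when a reference is supplied, with the conventional two-fold
acceptance window.

## Classifier

At sampling time t, concentrations are rounded to the nearest 100 ng/mL
(half-up at exact midpoints — the rounding direction is unspecified in the
source description). The conditional table is the count ratio per phenotype
over the contiguous bin range spanned by the training data plus two guard
bins at each end (floored at 0 ng/mL); a smoothing pseudo-count (default
0.5) is added per bin so posteriors exist for unseen concentrations:

    P(C|e_j) = (n_j(C) + s) / (n_j + s·B)

With s = 0 this is exactly the raw count ratio; an all-zero likelihood then
falls back to the nearest populated bin (bin distance, ties toward the
higher concentration) — a test-dose tool must always return a call. Queries
outside the trained range clamp to the guard bins, so very high
concentrations are scored like the highest trained bin (in practice PM).

Posteriors follow Bayes' rule with priors normalized to sum to 1 (default
uniform 1/3, matching equal-size training cohorts; population-frequency
priors are a config option). The MAP call breaks exact ties toward the
slower metabolizer (PM > IM > EM, tolerance 1e−12 relative): clinically
conservative, since a tied call escalates to dose-reduction review; the
`tie_flag` preserves auditability. Trained models serialize to JSON with bin
centers, counts, probabilities, priors, smoothing and provenance, and
classification is bit-stable across save/load.

## Evaluation

Confusion matrices are raw 3×3 counts (true × predicted); rows with zero
count are reported as undefined, never imputed. Sensitivity and specificity
are exact rational count fractions converted to float at the end, and the
false-positive probability is formed as `1.0 − specificity` so the pair sums
to 1 exactly. ROC points are computed per (time, phenotype) with the
classifier trained per time on the training cohort only. The published
optimal-time selection was visual ("P(+|+) close to 1, P(+|−) close to 0");
here it is scalarized as Youden's J = tpr − fpr, ties broken toward the
later time (logistically simpler, and the later time is the published
choice). Development-style probabilities are computed in-sample on the
training cohorts (mirroring the published development numbers); blinded
verification classifies a mixed cohort with labels withheld and joins truths
only for scoring — calls are byte-identical with or without the truth file.

The blinded cohort defaults to 100 subjects at the published Caucasian
phenotype frequencies "46% EM, 38% IM, 26% PM"; these sum to 110%, so the
normalized triple (0.418, 0.345, 0.236) is used — the intended triple is
unknowable from the source.

## What the generator does and does not emulate

It emulates: phenotype-dependent exposure after a single 600 mg dose with
realistic between-subject spread, calibrated so AUC/Cmax/CL population means
match the published predicted values within sampling noise (verified at
10×500 scale to within 10%); trial-structured designs; blinded mixed
cohorts. It does **not** emulate: multiphasic (distribution-phase) decline,
absorption lag or transit compartments, autoinduction, assay quantification
limits, covariate effects (sex, weight, race) or multiple dosing.

The main visible consequence: with AUC, Cmax and CL pinned to their targets,
a one-compartment model forces a single effective half-life (≈ 15 h for EM),
so EM concentrations at 24 h center near 800–900 ng/mL rather than falling
mostly below 500 ng/mL as the multiphasic PBPK profiles did. Phenotype
overlap at 24 h is therefore larger than in the original study: the 24 h
sample is still clearly the optimal choice (PM Youden J rises monotonically
with time), and EM remains the MAP call below 500 ng/mL, but the PM
posterior only exceeds 0.6 above ≈ 1,400 ng/mL (not 1,000), and in-sample PM
sensitivity at 24 h is ≈ 0.71 rather than 0.82. A green classifier test here
establishes correctness of the Bayesian machinery on the calibrated
surrogate world, not clinical performance. The in-sample PM sensitivity is
also seed-sensitive in a bimodal way (≈ 0.71–0.73 usually, ≈ 0.62 when the
contested 1,400–1,500 ng/mL bins flip to IM), because the empirical IM and
PM bin densities are nearly equal there.

## Numerical choices

- Quadrature: 24 Gauss–Hermite nodes per lognormal axis (13,824 product
  nodes) for the calibration objective; Brent tolerance 1e−3 L on mean_v.
- Probability normalization asserted to 1e−9; MAP tie tolerance 1e−12
  relative.
- Output formatting: probabilities to 4 decimals, concentrations to 1, for
  diff-stable regression of pipeline outputs.
- Degenerate inputs: negative concentrations and times rejected; empty
  phenotype mixes rejected; <2 trials rejected for interval estimation;
  single-phenotype evaluation cohorts yield flagged undefined confusion rows.

## Known limitations

- Clinical verification against the original 36-subject dataset is
  impossible (private data); performance is demonstrated only on synthetic
  cohorts from the surrogate.
- The surrogate's 24 h marginals are right-shifted for EM (above), so
  absolute decision thresholds from this package should not be applied
  clinically.
- Binned empirical likelihoods are noisy near decision boundaries; kernel or
  parametric likelihoods would stabilize them but are out of scope.
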