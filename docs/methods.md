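# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, the numerical choices and the known limitations of `lefpon`.

## Clinical scoring

Disease activity is the four-variable DAS28-ESR,
`0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln ESR + 0.014·VAS`, with the tender and
swollen joint counts on 0–28, ESR in mm/h (strictly positive, since its
logarithm is taken) and the pain VAS in millimetres on 0–100 — the 0.014
coefficient is only consistent with the mm scale. The CRP-based DAS28
variant and ACR/SDAI/CDAI criteria are out of scope.

EULAR response from (baseline, month-6) DAS28: *good* iff ΔDAS28 > 1.2 and
endpoint ≤ 3.2; *non-response* iff ΔDAS28 ≤ 0.6, or 0.6 < ΔDAS28 ≤ 1.2 with
endpoint > 5.1; *moderate* otherwise. The middle band is half-open:
an improvement of exactly 0.6 is non-response regardless of endpoint,
matching the standard EULAR table and removing the boundary overlap that a
closed band would create. Good and moderate are pooled into responder = 1,
non-responder = 0; this coding is used as the outcome everywhere.

When a cohort file carries both raw visit components and precomputed
DAS28 values, the raw components win and a disagreement above 0.01 is
logged.

## Statistical kernel

* **Pearson χ²** with expected counts `row·col/N` and **no continuity
  correction** anywhere — the published genotype-association statistics
  (4.404 / 4.314 / 0.223) are only reproduced without Yates' correction.
  Zero margins are rejected with the offending label.
* **Odds ratios** use the Woolf log-method: `OR = ad/bc`,
  `CI = exp(ln OR ∓ z·√(1/a+1/b+1/c+1/d))`; the Haldane–Anscombe +0.5
  correction is applied only when a zero cell occurs and the caller opts
  in. No exact or profile-likelihood intervals.
* **Logistic regression** is Newton–Raphson/IRLS with tolerance 1e-8 on
  the max absolute coefficient change, at most 100 iterations, Wald
  standard errors from the inverse observed information, and separation
  detection: any |coefficient| exceeding 15 during iteration raises an
  error rather than returning a divergent fit. Non-convergence is flagged
  and flagged fits are not reported. A singular information matrix
  (collinear design) falls back to minimum-norm steps and pseudo-inverse
  standard errors so that collinearity diagnostics can still be attached.
  With a single binary predictor the fit reproduces the closed-form 2×2
  odds ratio and Woolf standard error to at least six decimals (tested).
* **Rank statistics** (Spearman, Kruskal–Wallis, Mann–Whitney) use
  mid-ranks for ties, tie-corrected variances, and asymptotic two-sided
  p-values (t approximation for Spearman, χ² for Kruskal–Wallis, normal
  without continuity correction for Mann–Whitney). These delegate to
  scipy.stats behind the module surface.
* **Hardy–Weinberg** is the Pearson goodness-of-fit test with the allele
  frequency estimated from the data and df = 1.
* All p-values are two-sided; the significance level is 0.05 and the
  covariate-screening threshold 0.2. No multiple-testing correction is
  applied anywhere, by design: the per-CpG stage is an exploratory screen.

A note on the allele-model χ²: recomputing it from the published genotype
counts gives 2.634 (p = 0.105), whereas the source table prints 2.643 with
the same p; the counts-derived value is the one this package produces.

## Genetic models

Codominant (CC/CT/TT), dominant (CC vs CT+TT), recessive (CC+CT vs TT) and
allele (C vs T, two alleles per subject) cross-tabulations, reference CC
or C. Crude Woolf ORs are computed per non-reference level; adjusted ORs
come from logistic fits with indicator coding plus age (years,
untransformed) and sex (female = 1). The allele model reports the crude OR
only: per-allele rows duplicate subjects, so "adjusting" a logistic fit on
2N pseudo-observations would misstate the information content — and the
published allele OR is exactly the crude Woolf computation anyway.

## Methylation categorisation and per-CpG association

Percentiles use linear interpolation between closest order statistics
(the common statistical-software default), so cutoffs are reproducible
bit-for-bit. Values strictly below the 25th percentile are *low*, strictly
above the 75th are *high*; ties at a cutoff are *medium*, which keeps each
tail at most 25% under heavy ties. A constant CpG yields all-medium with a
warning.

The primary per-CpG effect is the ordinal hypomethylation coding
(high = 0, medium = 1, low = 2) in an age/sex-adjusted logistic fit; with
responder = 1 this makes OR > 1 mean "less methylation, better response".
Pairwise indicator contrasts (medium vs low, high vs low) and the 3×2
category-by-outcome χ² are reported alongside, because published per-site
odds ratios of this kind do not always state their coding; both codings
are available and the direction is what is verified in simulation.

## Composite genetic protective score

Per scored CpG: hyper = 0, intermediate = 1, hypo = 2; genotype: TT = 0,
CT = 1, CC = 2 (C is the putatively protective allele). The default scored
set is the nine significant sites (cg17330251_2, 3, 4, 6, 7, 8, 9, 10,
12), so the score spans 0–20. The score enters the models as its cohort
quartile category coded 1–4 (the raw sum is available behind
`score_coding="raw"`, since a per-unit interpretation of a published score
OR can be ambiguous). Model 1 is outcome ~ score; Model 2 adds every
covariate retained by the univariate *P* < 0.2 screen — the screen is
recomputed from the data on each run, not fixed to any particular
published set. Collinearity is assessed by variance inflation factors with
a flag threshold of 5; perfect collinearity reports an unbounded VIF.

## Synthetic-cohort generator

The generator's defaults are the study conditions; they are not tuned per
run.

* **Genotypes**: Hardy–Weinberg draws at C-allele frequency 0.525 (the
  pooled estimate from the published genotype counts), n = 240.
* **Methylation (ASM)**: one latent level per patient from a
  genotype-specific Beta distribution whose quartiles target
  CC 0.229 (0.195–0.287), CT 0.363 (0.332–0.395), TT 0.531 (0.496–0.557).
  The Beta parameters come from a weighted least-squares inversion of the
  quantile function; two shape parameters cannot match three arbitrary
  quantiles exactly (the skewed CC triple has a minimax residual of about
  0.005), so the median is up-weighted (20×) — recovered medians are then
  exact to ~5e-5 while the IQR absorbs a residual of up to ~0.011, which
  the fitted parameters report. The 12 site values are built on the logit
  scale as latent + per-site offset (centred, spanning ±0.15) + Gaussian
  site noise with sd `site_sd·√(1−site_corr)` (defaults 0.3 and 0.8),
  then transformed back and clipped strictly inside (0, 1). ASM is
  modelled at the patient level — genotype sets the latent level, sites
  jitter around it — with no per-allele haplotype phasing, the simplest
  structure consistent with per-genotype medians.
* **Outcome**: ΔDAS28 = 1.2 − 1.1·(centred average methylation) + N(0, 1).
  The slope −1.1 was chosen analytically: with the mixture sd of average
  methylation ≈ 0.12 implied by the genotype frequencies and the Beta
  spreads, it yields a population Spearman correlation of ≈ −0.13 between
  average methylation and ΔDAS28, the magnitude the analysis is meant to
  recover. The mean improvement 1.2 and noise sd 1.0 put the responder
  fraction in the 0.6–0.7 range at n = 240. Baseline DAS28 is normal
  (mean 5.2, sd 0.9) truncated to [2, 8.5].
* **Visits**: raw TJC/SJC/ESR/VAS are back-solved from each target DAS28 —
  VAS and ESR shares are drawn first (15–25% and 30–40% of the target),
  the remainder is apportioned to the joint counts with rounding, and the
  rounding residual is absorbed back into the continuous VAS. The
  recomputed DAS28 differs from its target by at most 0.15 (tested over
  the full target range).
* **Demographics and hematology**: age normal (55, 10²) truncated to
  [18, 90]; 80% female (RA is far more prevalent among women); blood
  counts log-normal with medians 4.0 / 1.8 / 0.45 / 260 ×10⁹/L for
  neutrophils / lymphocytes / monocytes / platelets and log-sd 0.25–0.35;
  plateletcrit derived as PLT·MPV/10⁶ with MPV ~ N(10 fL, 1). The source
  study publishes no distributions for these; the values are ordinary
  adult reference ranges and are calibration knobs, not claims about any
  real population.
* **Determinism**: one seeded generator, fixed draw order (age, sex,
  genotypes, methylation, outcomes, hematology); cohorts are
  bit-reproducible given the seed.

`null_config()` switches every association off (genotype-independent
methylation, zero methylation effect) and is the basis of the
type-I-error and coverage checks.

### What the generator does and does not emulate

It reproduces the *statistical skeleton*: HWE genotypes, ordered
genotype-conditional methylation, a weak negative methylation–ΔDAS28
correlation, plausible hematology and a realistic responder fraction. It
does **not** emulate bisulfite-conversion or measurement error,
longitudinal trajectories beyond two visits, population stratification,
linkage with the other promoter SNPs, or any genotype effect on outcome
beyond the methylation path. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes from data that contain it — not
that the biological findings replicate in new patients.

## Missing data

The source analysis used multiple imputation for variables with <10%
missingness; this package deliberately defaults to complete-case analysis
with a logged count (plus an optional single median imputation switch).
Full multiple imputation is out of scope, and with synthetic cohorts there
is no missingness unless injected.

## Problem sizes used in verification

Unit and acceptance tests use: 200 default cohorts of n = 240 for signal
recovery (median ordering and Spearman band), one n = 5,000 cohort for
median recovery within ±0.02, 1,000 null cohorts for type-I error
([0.03, 0.07] at α = 0.05) and Model-1 CI coverage (93–97%), and 60–200
seeds for direction-recovery checks. The acceptance script uses 120
calibration seeds, one n = 5,000 recovery cohort and 400 null replicates.
All replicate seeds are fixed or derived from the single `--seed`
argument, so every reported number is reproducible.

## Known limitations

* The published adjusted odds ratios (per-CpG ≈ 0.42–0.49 and the
  multifactor score/SIRI estimates) require the unreleased subject-level
  data and cannot be recomputed; the package verifies directions and
  calibration in simulation instead.
* Wald inference throughout; small-sample logistic fits (n ≲ 30) can be
  unstable and are surfaced via warnings or separation errors rather than
  silently reported.
* The Beta quantile inversion trades IQR fidelity (≤ ~0.011) for exact
  medians, as documented above.
* The generator's hematology and baseline-DAS28 distributions are
  conventional defaults, not estimates from the study population.
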