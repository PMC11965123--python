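# lefpon

Pharmaco-epigenetic association analysis of **leflunomide (LEF) response in
rheumatoid arthritis (RA)**, centred on the *PON1* promoter: the CpG island
probe **cg17330251** (12 measurable CpG sites) and the promoter SNP
**rs705379 (−108C>T)** that sits inside it. The package is written for
biostatisticians and pharmacogenetics researchers who want to run — or
stress-test on synthetic data — the full analysis chain linking
allele-specific DNA methylation (ASM) to a 6-month treatment-response
outcome.

## What it computes

**Clinical response.** Disease activity per visit is the four-variable
DAS28-ESR,

```
DAS28 = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln ESR + 0.014·VAS
```

and response to 6 months of LEF is the EULAR classification from the
improvement ΔDAS28 = DAS28(baseline) − DAS28(month 6): *good* if
ΔDAS28 > 1.2 with endpoint ≤ 3.2; *non-response* if ΔDAS28 ≤ 0.6 or if
0.6 < ΔDAS28 ≤ 1.2 with endpoint > 5.1; *moderate* otherwise. Good and
moderate responders are pooled into a binary responder flag (non-responder
coded 0). Blood-count inflammation indices NLR, PLR, SII and SIRI are
computed from neutrophil, lymphocyte, monocyte and platelet counts.

**Genetic association.** Genotype-by-response cross-tabulations at
rs705379 under codominant, dominant (CC vs CT+TT), recessive (CC+CT vs TT)
and allele (C vs T) models, with Pearson χ² (no continuity correction),
crude Woolf odds ratios against the CC / C reference, age- and sex-adjusted
logistic odds ratios, and a Hardy–Weinberg equilibrium χ² test.

**Methylation analysis.** Each CpG is cut at its cohort 25th/75th
percentiles into low / medium / high methylation; per-CpG association with
response uses an ordinal hypomethylation coding (high = 0, medium = 1,
low = 2) in an age/sex-adjusted logistic model, pairwise contrasts against
the low category, and a 3×2 χ². Patient-level average methylation over the
12 sites is summarised per genotype (median, IQR, Kruskal–Wallis) and
correlated with ΔDAS28 (Spearman).

**Composite genetic protective score.** Each significant CpG contributes
0/1/2 (hyper/intermediate/hypo-methylation) and the genotype contributes
0/1/2 (TT/CT/CC); the sum (0–20 with the nine significant sites) is
categorised into cohort quartiles. Model 1 regresses response on the score
term; Model 2 adds covariates retained by a univariate *P* < 0.2 screen,
with variance inflation factors as the collinearity check.

**Synthetic cohorts.** A generator reproduces the ASM structure the
analysis assumes — Hardy–Weinberg genotypes, genotype-conditional Beta
methylation (medians 0.229 / 0.363 / 0.531 for CC / CT / TT), a negative
methylation→ΔDAS28 effect calibrated to a Spearman *r* ≈ −0.13, and
log-normal hematology — so every stage runs and is verified without any
patient data.

## Worked example

```python
from lefpon import AnalysisConfig, run_pipeline

report = run_pipeline(AnalysisConfig(outdir="demo", seed=2))
for stage in report.stages:
    print(stage)
```

```
{'stage': 'load_cohort', 'n_in': 240, 'n_out': 240}
{'stage': 'clinical_scores', 'n_in': 240, 'n_out': 240, 'responders': 159}
{'stage': 'univariate_screen', 'n_in': 9, 'n_out': 3, 'retained': ['neut', 'nlr', 'sii']}
{'stage': 'genetic_association', 'n_in': 240, 'n_out': 4, 'hwe_p': 0.3893659053716987}
{'stage': 'cpg_association', 'n_in': 240, 'n_out': 12}
{'stage': 'methylation_genotype', 'n_in': 240, 'n_out': 3, 'spearman_r': -0.11579454504418477}
{'stage': 'multifactor_models', 'n_in': 240, 'n_out': 2, 'score_coding': 'quartile'}
```

The run simulates a 240-patient cohort (159 responders here), screens the
blood-count covariates at *P* < 0.2, and writes six report tables (plus
the simulated cohort and a run report) under `demo/`. In
`methylation_by_genotype.csv` the per-genotype medians of average
methylation come out ordered CC < CT < TT (0.231, 0.358, 0.539 for this
seed) with Kruskal–Wallis *P* ≈ 1e-39 — the allele-specific methylation
signal — and average methylation correlates negatively with ΔDAS28
(*r* = −0.116). In `multifactor_models.csv` the Model-1 protective score
term is, for this seed, OR 1.159 (95% CI 0.909–1.476) per score quartile:
higher protective scores (hypomethylated sites, CC genotype) trend toward
better response.

The same run is available from the shell:

```sh
lefpon pipeline --seed 2 --out demo          # simulate + analyze
lefpon simulate --seed 2 -n 240 --out c.csv  # cohort file only
lefpon analyze --input c.csv --out demo      # analysis only
lefpon fixtures table1 --out t1.csv          # published-counts cohort
```

## Layout

```
src/lefpon/
  stats.py        χ², Woolf OR, logistic IRLS, rank tests, HWE
  clinical.py     DAS28, EULAR categories, NLR/PLR/SII/SIRI
  simulate.py     synthetic ASM cohort generator
  association.py  four genetic models at rs705379
  methylation.py  quartile categorisation, per-CpG association
  score.py        composite protective score, Models 1–2, VIF
  io.py           cohort-table schema, read/write
  pipeline.py     orchestration, published-counts reconstruction fixture
  cli.py          `lefpon` command-line interface
docs/methods.md   model, generator and numerical documentation
```
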