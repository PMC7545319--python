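# tics

Tumor-infiltrating immune-cell prognostic scoring for bulk transcriptomics.

Immune-cell composition of the tumor microenvironment carries prognostic
information that TNM-style staging misses: cytotoxic and helper
populations can favor survival while inflammatory infiltrates can worsen
it. This package builds a **tumor immune cell score (TICS)** from bulk
expression cohorts with survival follow-up: single-sample GSEA (ssGSEA)
quantifies the relative infiltration of 28 immune-cell populations per
patient, each cell's prognostic effect is estimated by median-split Cox
regression independently in every training cohort, the per-cohort hazard
ratios are pooled by inverse-variance fixed-effects meta-analysis, and
the cells with significant pooled effects are combined into a weighted
per-patient score

```
TICS = Σᵢ (1 − HRᵢ) / SE(HRᵢ) × ESᵢ
```

where `HRᵢ` is the pooled hazard ratio of immune cell *i*, `SE(HRᵢ)` its
delta-method standard error, and `ESᵢ` the cell's (Z-standardized) ssGSEA
enrichment score. Protective cells (HR < 1) receive positive weights,
risk cells negative ones. Patients are stratified at a maximally
selected log-rank cutpoint, and the score is evaluated against tumor
mutational burden (TMB), cytolytic activity (CYT = √(GZMA × PRF1)), and
chemotherapy response (CR vs non-CR ROC, two-score logistic combination).

Everything is testable without external downloads: a synthetic
multi-cohort generator plants known risk/protective cells, couples
mutation counts negatively to protective immunity, and draws complete
responses logistic in the protective risk component, so recovery of the
planted structure can be measured end to end.

Audience: computational oncology / bioinformatics researchers building or
benchmarking immune prognostic signatures from bulk expression cohorts.

## Worked example

`examples/02_train_signature.py` generates four cohorts of 150 patients
with six planted prognostic cells (|log HR| = 0.6) and trains the
signature:

```
selected prognostic cells and their (1 - HR)/SE(HR) weights:
  Activated B cell             +8.10
  Monocyte                     +5.92
  Type 17 T helper cell        +4.71
  Macrophage                   +3.47
  Neutrophil                   -3.42
  Effector memory CD8 T cell   +2.83
  Activated CD4 T cell         -2.59

per-cohort log-rank p of the high/low TICS strata:
  SYN1: chi2 =   64.42, p = 1.01e-15
  SYN2: chi2 =   47.33, p = 6.01e-12
  SYN3: chi2 =   41.02, p = 1.51e-10
  SYN4: chi2 =   49.69, p = 1.80e-12
```

All six planted cells are recovered with correctly signed weights — the
four protective cells positive, the two risk cells negative — plus one
spurious cell, the order of magnitude expected from testing 28 cells at
α = 0.05. Applying the frozen weights to a held-out fifth cohort
(`examples/03_validate_holdout.py`) gives

```
log-rank chi2 = 45.13, p = 1.84e-11
concordance index (higher TICS ~ longer survival): 0.719
```

so the signature transfers to data it was never trained on. The other
examples cover ssGSEA basics, stratum characterization (TMB/CYT,
per-gene mutation contrasts), and chemosensitivity prediction.

A thin CLI mirrors the library:
`tics simulate | train | apply | characterize | chemo` (see `tics --help`).

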