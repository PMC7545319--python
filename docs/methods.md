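# Methods

## The score

The pipeline estimates, for each of 28 immune-cell populations, whether
its relative infiltration is associated with overall survival, and
combines the significant cells into one per-patient score.

**Infiltration.** ssGSEA scores one gene set in one sample from the
within-sample expression ranks: genes are walked in decreasing-rank
order, in-set positions add `rank^α` (normalized so the in-set
increments sum to 1), out-set positions subtract `1/(N − |S|)`, and the
enrichment score is the sum of the running difference over all N
positions. Because both step types are normalized, the running sum ends
exactly at 0, and the score equals the closed form
`Σⱼ (N − j + 1)·stepⱼ`, which the engine evaluates as two matrix
products. The score is invariant to any strictly monotone per-sample
transform of the expression values, which is why no cross-platform
normalization is required beyond a log2-scale input.

**Per-cohort effects.** Within each training cohort, each cell's
enrichment scores are split at the cohort median and the high/low
indicator enters a univariate Cox proportional-hazards model (Newton-
Raphson on the partial likelihood; Efron tie handling by default,
Breslow available). Wald standard errors come from the inverse observed
information.

**Pooling.** Per-cohort log hazard ratios are pooled with
inverse-variance fixed-effects weights: `β̂ = Σ wₖβₖ / Σ wₖ`,
`wₖ = 1/seₖ²`, `se(β̂) = (Σ wₖ)^(−1/2)`; Cochran's Q and I² are reported
as heterogeneity diagnostics. Cells with pooled two-sided p < 0.05
(raw; a Benjamini–Hochberg variant is available behind a flag) form the
signature.

**Weights and score.** Each selected cell contributes weight
`wᵢ = (1 − HRᵢ)/SE(HRᵢ)` with `HRᵢ = exp(β̂ᵢ)` the pooled hazard ratio.
`SE(HRᵢ)` defaults to the delta-method SE on the hazard-ratio scale
(`HRᵢ·se(β̂ᵢ)`); dividing by the log-scale SE instead is a flag, since
the formula's scale is a genuinely open choice and the recovery suite
passes under both. The per-sample raw score is `Σᵢ wᵢ·ESᵢ` with each
cell's enrichment Z-standardized within cohort first (default on — it
makes training weights portable to cohorts whose raw enrichment scale
differs), and the final score is Z-normalized within cohort.

**Stratification.** High/low groups come from the maximally selected
log-rank cutpoint: all midpoints between consecutive sorted unique
scores are scanned, thresholds leaving either group below `minprop`
(default 0.1) of the samples are discarded, and the threshold maximizing
the absolute standardized log-rank statistic wins (ties break toward the
median). Because the maximizing threshold is selected on the same data,
the log-rank p at the cutpoint is optimistic; an optional permutation
p-value (≥ 1000 label permutations of the maximal statistic) gives an
honest test. Train/apply separation is strict: validation cohorts are
scored with the frozen weights JSON and training ssGSEA parameters; only
the cohort-specific cutoff is re-derived.

**Auxiliary quantities.** TMB = coding-flagged SNV/INS/DEL count per
sample divided by `coding_mb` (default 38 Mb, the common exome
convention; every TMB comparison in the pipeline is rank-based so the
constant cancels). CYT = √((GZMA + ε)(PRF1 + ε)) on the linear scale
(ε = 0.01 guards zero expression); log2 input is back-transformed first.
Group comparisons use the two-sided Wilcoxon rank-sum (exact null when
n ≤ 25 and tie-free, normal approximation otherwise; Student's t behind
a flag) with BH adjustment across features. Per-gene mutation-frequency
contrasts use the 2×2 chi-square with continuity correction, falling
back to Fisher's exact test when any expected cell is below 5. The
time-dependent AUC is the cumulative/dynamic estimator with inverse-
probability-of-censoring weights from the censoring Kaplan–Meier curve.
ROC AUCs are Mann–Whitney pair counts with ties worth 1/2; the two-score
combiner is an unpenalized logistic model on the standardized scores,
reporting the in-sample AUC (a documented caveat — no optimism
correction is applied by default).

## Synthetic study conditions

The generator emulates the structure the analysis assumes, with ground
truth attached. Defaults are the recovery scenario used throughout the
tests: 4 training cohorts × 150 patients, 500 genes, 28 cells with 10
disjoint marker genes each, and six planted cells at |γ| = 0.6 — two
risk (activated CD4 T cells, neutrophils) and four protective
(monocytes, activated B cells, macrophages, Th17), matching the
directions reported for pancreatic ductal adenocarcinoma.

- **Abundance.** Latent cell abundance is log-normal,
  `log a ~ N(0, 0.5²)` per (cell, sample), independent across cells.
- **Expression.** Member gene g of cell c:
  `baselineᵍ + log a_c + N(0, 1)` (log2 units, baselines `N(7, 2²)`);
  non-member genes are baseline plus noise. The unit link keeps
  within-sample ranks of marker genes tracking abundance, so ssGSEA
  recovers it. The two cytolytic effector genes (GZMA, PRF1) track
  activated-CD8 abundance. Marker blocks are disjoint by default (an
  `overlap_fraction` shares part of each block with the next cell).
- **Survival.** Exponential proportional hazards:
  `λ = 0.03·exp(Σ_c γ_c·z(a_c))` events/month with z the within-cohort
  standardized log abundance, independent exponential censoring at
  0.02/month: median survival ≈ 23 months and ~35–40% censoring,
  pancreatic-cancer-like. Time is months in every cohort.
- **Mutations.** Per-sample coding count
  `Poisson(exp(log 76 − 0.5·protective burden))` — mean TMB 2/Mb over a
  38 Mb exome — with genes drawn from a fixed per-mutation frequency
  list giving realistic carrier fractions (KRAS ~90%, TP53 ~60%) over
  400 passenger genes; a few Silent records exercise the coding filter.
  The negative coupling to the mean standardized abundance of the
  protective cells reproduces the negative TICS–TMB association.
- **Chemotherapy.** Each patient receives chemotherapy with probability
  0.5; responders get CR with probability
  `logistic(−1 + 1·protective LP)`, non-CR splits 0.3/0.4/0.3 among
  PR/SD/PD; untreated patients are `unknown`. With
  `chemo_interaction=True` the survival linear predictor is active only
  in the treated arm, the scenario behind the within-arm contrast
  property.
- **Seeding.** The global seed expands through `SeedSequence` spawn keys
  `(cohort, stream)`; adding a cohort never perturbs earlier ones, and
  identical (config, seed) is bit-identical.

The planted effect size |γ| = 0.6 is a calibration choice, not an
estimate of any real cohort; real signatures also overlap in genes,
carry batch and platform effects, and violate proportional hazards in
ways the generator does not model. Passing recovery tests therefore
demonstrate that the estimator chain is correct and well calibrated
under its own assumptions, not that the score attains any particular
performance on real tumors.

## Numerical choices

- ssGSEA: α = 0.25 and whole-matrix (max − min) normalization, the
  conventional defaults of the method's reference toolchain; both
  exposed. Walk ties in rank break lexicographically by gene id for
  cross-platform determinism. Sets intersecting the matrix in fewer than
  5 genes are skipped with a warning; absent genes are dropped, not
  imputed. Gene symbols match case-insensitively, exact case preferred.
- Cox: convergence at max |score| < 1e−9 or |Δβ| < 1e−10, ≤ 50
  iterations with step-halving; |β| > 15 is treated as monotone
  likelihood, capped, and flagged. A vectorized fast path handles the
  tie-free case (where Efron and Breslow coincide).
- Median dichotomization sends ties at the median to the low group.
- Kaplan–Meier counts censorings at an event time as still at risk; a
  censored-at-2 subject in times {1, 2, 3}, events {1, 0, 1} leaves the
  t = 3 risk set, so S drops to (1 − 1/3)(1 − 1/1) = 0.
- Fixed-effects pooling requires ≥ 2 cohort estimates; cohorts under 10
  usable samples are excluded from per-cell Cox with a warning, and a
  cell constant within a cohort yields a missing entry rather than a
  failure.
- Duplicate expression gene rows collapse by max (preserves detection of
  an expressed transcript); survival times convert days↔months at 30.44.

## Test scale

Simulation-based checks run at deliberately modest sizes chosen for a
single CPU: 50 replicates for the recovery property, 2000 for log-rank
calibration (n = 150), 150 × 28 cells for selection calibration
(4 cohorts × 100 samples, 145 genes), 200 × n = 500 for Cox
consistency. `scripts/acceptance.py` uses 20 recovery replicates and
1000 calibration replicates.

One calibration fact worth knowing: with 22 truly null cells tested at
raw α = 0.05, about one spurious cell per training run is expected
(`0.95²² ≈ 0.32` probability of none). The recovery suite's
zero-false-positive requirement is therefore unattainable under raw
selection while the per-cell test stays calibrated at 0.05 — the
corresponding acceptance test documents this and fails on that single
clause; sensitivity, weight signs, and held-out transfer all hold. Use
the BH selection flag when a conservative cell list matters.

## Known limitations

- No microarray/RNA-seq noise models, batch effects, or copy-number
  events in the generator; no competing risks, stratified/frailty Cox,
  or proportionality diagnostics; no permutation significance for
  ssGSEA scores.
- The combination AUC is in-sample; bootstrap optimism correction is
  left to the caller.
- The maximally selected cutpoint's nominal log-rank p is optimistic by
  construction; rely on the permutation p-value or external validation.
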