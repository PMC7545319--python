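"""Apply frozen training weights to a held-out cohort.

Mirrors the train/validate design: weights learned on four cohorts are
applied unchanged to a fifth cohort that the training never saw; only
the cohort-specific cutoff is re-derived.
"""

import dataclasses

from tics import GeneratorConfig, concordance_index, generate_dataset, run_apply, run_train

config = GeneratorConfig(seed=1)
bundles, _, gene_sets = generate_dataset(config)
trained = run_train(bundles, gene_sets, seed=1)

holdout_config = dataclasses.replace(config, n_cohorts=config.n_cohorts + 1)
holdout = generate_dataset(holdout_config)[0][-1]  # the new 5th cohort

applied = run_apply(trained.weights, holdout, gene_sets, seed=1)
cindex = concordance_index(
    holdout.survival,
    applied.score.z.reindex(holdout.survival.sample_ids).to_numpy(),
)

print(f"held-out cohort: {applied.cohort}  (n = {len(applied.strata)})")
print(f"TICS cutoff: {applied.cutoff:+.3f}")
print(f"high / low strata sizes: {int(applied.strata.sum())} / "
      f"{int((1 - applied.strata).sum())}")
print(f"log-rank chi2 = {applied.logrank[0]:.2f}, p = {applied.logrank[1]:.2e}")
print(f"concordance index (higher TICS ~ longer survival): {cindex:.3f}")
# A C-index well above 0.5 and a small log-rank p confirm the frozen
# signature transfers to data it was not trained on.
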