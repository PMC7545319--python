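"""End-to-end orchestration: train on multiple cohorts, apply frozen
weights to validation cohorts, characterize strata, and evaluate
chemosensitivity.

The training product is a frozen :class:`~tics.meta.TICSWeights` artifact;
applying it to a new cohort uses nothing from training beyond the weights
and the ssGSEA parameters (the cohort-specific cutoff is re-derived).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aux import compute_cyt, compute_tmb, group_compare, mutation_freq_compare, spearman_assoc
from .chemo import chemo_survival_contrast, combine_scores, compare_response_groups, roc_auc
from .io import CohortBundle, GeneSetCollection
from .meta import (
    TICSScore,
    TICSWeights,
    compute_tics,
    compute_weights,
    per_cohort_cell_cox,
    pool_cox_table,
    select_prognostic_cells,
    stratify_tics,
)
from .ssgsea import ssgsea_matrix
from .survival import km_estimate, optimal_cutoff

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "TrainResult", "ApplyResult", "run_train", "run_apply",
           "run_characterize", "run_chemo"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cohort id."""

    def __init__(self, stage: str, cohort: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for cohort {cohort or '<all>'}: {cause}")
        self.stage = stage
        self.cohort = cohort
        self.cause = cause


@dataclass
class TrainResult:
    weights: TICSWeights
    cox_table: pd.DataFrame  # per cell x cohort
    forest: pd.DataFrame  # pooled effects, one row per cell
    scores: dict[str, TICSScore]  # cohort -> per-sample scores
    strata: dict[str, pd.Series]  # cohort -> high/low labels
    cutoffs: dict[str, float]
    logrank: dict[str, tuple[float, float]]  # cohort -> (chi2, p)


@dataclass
class ApplyResult:
    cohort: str
    score: TICSScore
    strata: pd.Series
    cutoff: float
    logrank: tuple[float, float]  # (chi2, p)
    km_high: object = None
    km_low: object = None


def _stage(stage: str, cohort: str = ""):
    """Decorator-free error wrapper for pipeline stages."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, cohort, exc) from exc
            return False

    return _Ctx()


def run_train(
    bundles: list[CohortBundle],
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
    minprop: float = 0.1,
    ssgsea_alpha: float = 0.25,
    se_scale: str = "hr",
    standardize_cells: bool = True,
    seed: int = 0,
) -> TrainResult:
    """Train the signature on >= 2 cohorts and score them.

    read -> ssGSEA -> median-split per-cell Cox -> fixed-effects pooling ->
    selection -> weights -> per-cohort scores -> maximally selected cutoffs.
    """
    if len(bundles) < 2:
        raise ValueError("meta-analysis requires >= 2 training cohorts")
    enrichments = []
    for b in bundles:
        with _stage("ssgsea", b.cohort_id):
            enrichments.append(ssgsea_matrix(b.expression, gene_sets, alpha=ssgsea_alpha))
    with _stage("per_cohort_cell_cox"):
        cox_table = per_cohort_cell_cox(bundles, enrichments)
    with _stage("pool_fixed_effects"):
        pooled = pool_cox_table(cox_table)
    selected = select_prognostic_cells(pooled, alpha=alpha)
    if not selected:
        raise PipelineError(
            "select_prognostic_cells", "", ValueError("no cell passed the selection alpha")
        )
    provenance = {
        "version": __version__,
        "seed": seed,
        "cohorts": [b.cohort_id for b in bundles],
        "ssgsea_alpha": ssgsea_alpha,
        "selection_alpha": alpha,
        "standardize_cells": standardize_cells,
    }
    weights = compute_weights(selected, alpha=alpha, se_scale=se_scale, provenance=provenance)

    forest = pd.DataFrame(
        [
            {
                "cell": e.cell,
                "k": e.k,
                "beta": e.beta,
                "hr": e.hr,
                "se_beta": e.se_beta,
                "se_hr": e.se_hr,
                "hr_ci_low": float(np.exp(e.beta - 1.96 * e.se_beta)),
                "hr_ci_high": float(np.exp(e.beta + 1.96 * e.se_beta)),
                "z": e.z,
                "p": e.p,
                "q": e.q,
                "i2": e.i2,
                "selected": e.cell in weights.weights,
                "direction": e.direction,
            }
            for e in pooled
        ]
    ).sort_values("p", kind="stable").reset_index(drop=True)

    scores, strata, cutoffs, logrank = {}, {}, {}, {}
    rng = np.random.default_rng(seed)
    for b, enrich in zip(bundles, enrichments):
        with _stage("compute_tics", b.cohort_id):
            sc = compute_tics(enrich, weights, cohort=b.cohort_id,
                              standardize_cells=standardize_cells)
        with _stage("stratify_tics", b.cohort_id):
            labels, cut, lr = stratify_tics(sc, b.survival, minprop=minprop, rng=rng)
        scores[b.cohort_id] = sc
        strata[b.cohort_id] = labels
        cutoffs[b.cohort_id] = cut.threshold
        logrank[b.cohort_id] = lr
    return TrainResult(
        weights=weights,
        cox_table=cox_table,
        forest=forest,
        scores=scores,
        strata=strata,
        cutoffs=cutoffs,
        logrank=logrank,
    )


def run_apply(
    weights: TICSWeights,
    bundle: CohortBundle,
    gene_sets: GeneSetCollection,
    minprop: float = 0.1,
    seed: int = 0,
) -> ApplyResult:
    """Score a held-out cohort with frozen weights.

    ssGSEA runs with the training parameters recorded in the weights
    provenance; only the cohort-specific cutoff is re-derived.
    """
    missing = [c for c in weights.cells if c not in gene_sets]
    if missing:
        raise PipelineError(
            "run_apply",
            bundle.cohort_id,
            ValueError(f"gene-set collection missing weighted cell(s): {missing}"),
        )
    ssgsea_alpha = float(weights.provenance.get("ssgsea_alpha", 0.25))
    standardize = bool(weights.provenance.get("standardize_cells", True))
    with _stage("ssgsea", bundle.cohort_id):
        enrich = ssgsea_matrix(bundle.expression, gene_sets, alpha=ssgsea_alpha)
    with _stage("compute_tics", bundle.cohort_id):
        score = compute_tics(enrich, weights, cohort=bundle.cohort_id,
                             standardize_cells=standardize)
    with _stage("stratify_tics", bundle.cohort_id):
        labels, cut, lr = stratify_tics(
            score, bundle.survival, minprop=minprop, rng=np.random.default_rng(seed)
        )
    km_high = km_low = None
    for label_value in (1, 0):
        ids = labels.index[labels == label_value]
        sub = bundle.survival.subset(ids)
        if sub.data["event"].sum() > 0:
            curve = km_estimate(sub)
            if label_value == 1:
                km_high = curve
            else:
                km_low = curve
    return ApplyResult(
        cohort=bundle.cohort_id,
        score=score,
        strata=labels,
        cutoff=cut.threshold,
        logrank=lr,
        km_high=km_high,
        km_low=km_low,
    )


def run_characterize(
    score: TICSScore,
    strata: pd.Series,
    bundle: CohortBundle,
    minprop: float = 0.1,
    min_count: int = 3,
) -> dict:
    """TMB/CYT associations, TMB x TICS strata, and mutation comparisons.

    Analyses whose input tables are absent are skipped with a note.
    """
    report: dict = {"cohort": bundle.cohort_id, "skipped": []}
    z = score.z

    try:
        cyt = compute_cyt(bundle.expression).cyt.reindex(z.index)
        if cyt.notna().all():
            rho, p = spearman_assoc(z.to_numpy(), cyt.to_numpy())
            report["spearman_tics_cyt"] = {"rho": rho, "p": p}
    except ValueError as exc:
        report["skipped"].append(f"cyt: {exc}")

    if bundle.mutations is None or bundle.mutations.data.empty:
        report["skipped"].append("mutation analyses skipped (no mutation table)")
    else:
        with _stage("tmb", bundle.cohort_id):
            tmb = compute_tmb(bundle.mutations, sample_universe=list(z.index)).tmb.reindex(z.index)
            rho, p = spearman_assoc(z.to_numpy(), tmb.to_numpy())
            report["spearman_tics_tmb"] = {"rho": rho, "p": p}
        with _stage("tmb_strata", bundle.cohort_id):
            try:
                tmb_cut = optimal_cutoff(
                    tmb.reindex(bundle.survival.sample_ids).to_numpy(),
                    bundle.survival,
                    minprop=minprop,
                )
                tmb_high = pd.Series(tmb_cut.labels, index=bundle.survival.sample_ids)
                combined = (
                    2 * tmb_high + strata.reindex(bundle.survival.sample_ids)
                )  # 0..3: (TMB,TICS) = (lo,lo),(lo,hi),(hi,lo),(hi,hi)
                medians = {}
                for code, name in [
                    (0, "tmb_low_tics_low"),
                    (1, "tmb_low_tics_high"),
                    (2, "tmb_high_tics_low"),
                    (3, "tmb_high_tics_high"),
                ]:
                    ids = combined.index[combined == code]
                    sub = bundle.survival.subset(ids)
                    if len(sub.data) and sub.data["event"].sum() > 0:
                        curve = km_estimate(sub)
                        # restricted mean over the observed grid as a one-number summary
                        medians[name] = _km_mean(curve)
                report["tmb_tics_strata_rmst"] = medians
            except ValueError as exc:
                report["skipped"].append(f"tmb strata: {exc}")
        with _stage("mutation_freq", bundle.cohort_id):
            try:
                report["mutation_freq"] = mutation_freq_compare(
                    bundle.mutations, strata, min_count=min_count
                )
            except ValueError as exc:
                report["skipped"].append(f"mutation freq: {exc}")

    with _stage("stratum_expression", bundle.cohort_id):
        expr = bundle.expression.values.loc[:, strata.index]
        # limit to the most variable genes for the stratum comparison table
        top = expr.var(axis=1).nlargest(min(50, expr.shape[0])).index
        report["stratum_gene_compare"] = group_compare(expr.loc[top], strata.to_numpy())
    return report


def _km_mean(curve) -> float:
    """Restricted mean survival time over the curve's event-time grid."""
    times = np.concatenate([[0.0], curve.times])
    surv = np.concatenate([[1.0], curve.survival])
    return float(np.sum(np.diff(times) * surv[:-1]))


def run_chemo(
    score: TICSScore,
    strata: pd.Series,
    bundle: CohortBundle,
    second_score: pd.Series | None = None,
) -> dict:
    """Chemosensitivity report: CR contrasts, ROC, arm-wise survival.

    ``second_score`` is any precomputed per-sample score to combine with
    (the role an external immune score plays); when absent, only the
    single-score ROC is reported.
    """
    if bundle.chemo is None:
        raise PipelineError("run_chemo", bundle.cohort_id, ValueError("no chemo table"))
    z = score.z
    report: dict = {"cohort": bundle.cohort_id}
    with _stage("response_groups", bundle.cohort_id):
        report["response_groups"] = compare_response_groups(z, bundle.chemo)
    with _stage("roc", bundle.cohort_id):
        known = bundle.chemo.data[bundle.chemo.data["response"] != "unknown"]
        labels = (known["response"] == "CR").astype(int).to_numpy()
        aligned = z.reindex(known["sample_id"]).to_numpy()
        roc = roc_auc(aligned, labels)
        report["roc_cr"] = {"auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg}
        if second_score is not None:
            second = pd.Series(second_score).reindex(known["sample_id"]).to_numpy()
            _, combo = combine_scores(aligned, second, labels)
            report["combined"] = combo
    with _stage("survival_contrast", bundle.cohort_id):
        report["survival_contrast"] = chemo_survival_contrast(strata, bundle.survival, bundle.chemo)
    return report


# ---------------------------------------------------------------------------
# artifact serialization with provenance headers


def provenance_header(config: dict, seed: int) -> str:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# tics v{__version__} | config {digest} | seed {seed}\n"


def write_train_artifacts(result: TrainResult, outdir: str | Path, config: dict, seed: int) -> None:
    """Write forest table, weights JSON, per-sample scores, and KM summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config, seed)

    result.weights.to_json(outdir / "weights.json")
    with open(outdir / "forest.tsv", "w") as fh:
        fh.write(header)
        result.forest.to_csv(fh, sep="\t", index=False)
    with open(outdir / "cox_table.tsv", "w") as fh:
        fh.write(header)
        result.cox_table.to_csv(fh, sep="\t", index=False)
    rows = []
    for cohort, sc in result.scores.items():
        frame = sc.scores.assign(
            cohort=cohort, stratum=result.strata[cohort].reindex(sc.scores["sample_id"]).values
        )
        rows.append(frame)
    with open(outdir / "scores.tsv", "w") as fh:
        fh.write(header)
        pd.concat(rows).to_csv(fh, sep="\t", index=False)
    summary = {
        cohort: {"cutoff": result.cutoffs[cohort], "logrank_chi2": result.logrank[cohort][0],
                 "logrank_p": result.logrank[cohort][1]}
        for cohort in result.scores
    }
    with open(outdir / "train_summary.json", "w") as fh:
        json.dump({"provenance": header.strip("# \n"), "cohorts": summary}, fh, indent=2)
        fh.write("\n")
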