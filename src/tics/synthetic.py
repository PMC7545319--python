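"""Synthetic multi-cohort generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: K
cohorts of bulk log2 expression driven by 28 latent immune-cell
abundances, exponential proportional-hazards survival with planted
risk/protective cells, independent exponential censoring, somatic
mutation counts negatively coupled to protective immunity, and
RECIST-style chemotherapy response labels logistic in the protective part
of the true linear predictor.

Each cell owns a disjoint block of marker genes (an optional overlap
fraction shares part of a block with the next cell).  For a member gene g
of cell c in sample s,

    expression = baseline_g + log(abundance_{c,s}) + N(0, noise_sd)

so within-sample ranks of marker genes track the latent abundance and
ssGSEA recovers it.  The hazard of sample s is

    lambda_0 * exp( sum_c gamma_c * z(abundance_{c,s}) )

with z the within-cohort standardization of the log abundance.  Time is
in months for every cohort.

Seeding: the global seed expands through ``numpy.random.SeedSequence``
spawn keys — cohort k draws from sub-streams (k, 0..4) for
abundance/expression, survival, mutations, chemo assignment, and response
labels — so adding a cohort never perturbs earlier cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChemoTable, CohortBundle, ExpressionMatrix, GeneSetCollection, MutationTable, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_NAMES",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohorts",
    "generate_mutations",
    "generate_chemo_labels",
    "generate_dataset",
    "cell_gene_sets",
]

#: The 28 immune-cell populations scored by the signature collection.
CELL_NAMES = (
    "Activated B cell",
    "Activated CD4 T cell",
    "Activated CD8 T cell",
    "Activated dendritic cell",
    "CD56bright natural killer cell",
    "CD56dim natural killer cell",
    "Central memory CD4 T cell",
    "Central memory CD8 T cell",
    "Effector memory CD4 T cell",
    "Effector memory CD8 T cell",
    "Eosinophil",
    "Gamma delta T cell",
    "Immature B cell",
    "Immature dendritic cell",
    "Macrophage",
    "Mast cell",
    "MDSC",
    "Memory B cell",
    "Monocyte",
    "Natural killer cell",
    "Natural killer T cell",
    "Neutrophil",
    "Plasmacytoid dendritic cell",
    "Regulatory T cell",
    "T follicular helper cell",
    "Type 1 T helper cell",
    "Type 17 T helper cell",
    "Type 2 T helper cell",
)
assert len(CELL_NAMES) == 28

#: Default planted prognostic cells: two risk (log-HR +0.6) and four
#: protective (log-HR -0.6), mirroring the directions reported for
#: pancreatic cancer (activated CD4 T cells and neutrophils harmful;
#: monocytes, activated B cells, macrophages, and Th17 protective).
DEFAULT_PLANTED = {
    "Activated CD4 T cell": 0.6,
    "Neutrophil": 0.6,
    "Monocyte": -0.6,
    "Activated B cell": -0.6,
    "Macrophage": -0.6,
    "Type 17 T helper cell": -0.6,
}

#: Per-mutation gene probabilities; with ~76 coding mutations per sample
#: these give pancreatic-cancer-like carrier fractions (KRAS ~90%,
#: TP53 ~60%, the rest lower), so KRAS is the high-frequency driver the
#: frequency-comparison operations need.  The remaining probability mass
#: is spread uniformly over passenger genes.
MUTATION_GENE_FREQS = {
    "KRAS": 0.030,
    "TP53": 0.012,
    "TTN": 0.006,
    "SMAD4": 0.004,
    "CDKN2A": 0.003,
    "MUC16": 0.003,
    "RNF43": 0.002,
    "ARID1A": 0.002,
    "GNAS": 0.002,
    "KMT2C": 0.002,
}

N_PASSENGER_GENES = 400

_NONCR_PROPS = {"PR": 0.3, "SD": 0.4, "PD": 0.3}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic multi-cohort dataset.

    Defaults are the recovery scenario used throughout the test suite:
    four training cohorts of 150 patients, 28 cells with 10 marker genes
    each inside a 500-gene matrix, and six planted prognostic cells at
    |log-HR| = 0.6.
    """

    n_cohorts: int = 4
    samples_per_cohort: int = 150
    n_genes: int = 500
    n_cells: int = 28
    genes_per_cell: int = 10
    planted_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    abundance_dispersion: float = 0.5  # sd of log abundance
    expression_noise_sd: float = 1.0  # log2 units
    baseline_hazard: float = 0.03  # events per month
    censoring_rate: float = 0.02  # censorings per month
    tmb_coupling: float = -0.5  # slope of log mutation rate on protective burden
    tmb_log_mean: float = float(np.log(76.0))  # mu0: log expected coding count
    coding_mb: float = 38.0
    chemo_intercept: float = -1.0
    chemo_slope: float = 1.0
    chemo_fraction: float = 0.5
    chemo_interaction: bool = False  # hazard link active only in the chemo arm
    overlap_fraction: float = 0.0  # fraction of a cell's genes shared with the next cell
    seed: int = 0

    def __post_init__(self) -> None:
        cells = CELL_NAMES[: self.n_cells]
        checks = [
            (self.n_cohorts >= 1, "n_cohorts must be >= 1"),
            (self.samples_per_cohort >= 2, "samples_per_cohort must be >= 2"),
            (self.genes_per_cell >= 3, "genes_per_cell must be >= 3"),
            (
                self.n_genes >= self.n_cells * self.genes_per_cell,
                "n_genes must be >= n_cells * genes_per_cell",
            ),
            (1 <= self.n_cells <= len(CELL_NAMES), f"n_cells must be in [1, {len(CELL_NAMES)}]"),
            (self.abundance_dispersion > 0, "abundance_dispersion must be > 0"),
            (self.expression_noise_sd > 0, "expression_noise_sd must be > 0"),
            (self.baseline_hazard > 0, "baseline_hazard must be > 0"),
            (self.censoring_rate > 0, "censoring_rate must be > 0"),
            (self.coding_mb > 0, "coding_mb must be > 0"),
            (0 <= self.overlap_fraction < 1, "overlap_fraction must be in [0, 1)"),
            (0 < self.chemo_fraction <= 1, "chemo_fraction must be in (0, 1]"),
            (
                set(self.planted_effects) <= set(cells),
                f"planted_effects keys must be cell names; "
                f"unknown: {sorted(set(self.planted_effects) - set(cells))}",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid GeneratorConfig: {msg}")

    @property
    def cells(self) -> tuple[str, ...]:
        return CELL_NAMES[: self.n_cells]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    cell_gene_assignment: dict[str, list[str]]
    latent_abundance: pd.DataFrame  # cells x all samples (positive)
    planted_effects: dict[str, float]
    true_linear_predictor: pd.Series  # per sample, risk scale
    protective_lp: pd.Series  # per sample; higher = better prognosis
    protective_burden: pd.Series  # mean standardized log-abundance of protective cells
    received_chemo: pd.Series  # per sample 0/1
    cohort_of: pd.Series  # sample -> cohort id
    seed: int


def _cohort_rngs(seed: int, k: int) -> list[np.random.Generator]:
    """Four independent streams for cohort k: abundance/expr, survival,
    mutations, chemo."""
    return [
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, j)))
        for j in range(4)
    ]


def cell_gene_sets(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Gene universe and the block assignment of marker genes to cells."""
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    gpc = config.genes_per_cell
    # when filler genes exist, name two of them after the cytolytic
    # effectors so CYT scoring is exercised on synthetic data
    if config.n_genes - config.n_cells * gpc >= 2:
        genes[-2], genes[-1] = "GZMA", "PRF1"
    assignment: dict[str, list[str]] = {}
    for c, cell in enumerate(config.cells):
        block = list(genes[c * gpc : (c + 1) * gpc])
        if config.overlap_fraction > 0:
            n_shared = int(np.ceil(config.overlap_fraction * gpc))
            nxt = (c + 1) % config.n_cells
            block += genes[nxt * gpc : nxt * gpc + n_shared]
        assignment[cell] = block
    return genes, assignment


def generate_cohorts(config: GeneratorConfig) -> tuple[list[CohortBundle], SyntheticTruth]:
    """Generate the K cohorts and their ground truth.

    Identical (config, seed) yields bit-identical output.
    """
    genes, assignment = cell_gene_sets(config)
    cells = list(config.cells)
    gamma = np.array([config.planted_effects.get(c, 0.0) for c in cells])
    protective_mask = gamma < 0

    bundles = []
    abundance_blocks, lp_blocks, prot_blocks, chemo_blocks, cohort_labels = [], [], [], [], []
    for k in range(config.n_cohorts):
        rng_expr, rng_surv, _, rng_chemo = _cohort_rngs(config.seed, k)
        cohort_id = f"SYN{k + 1}"
        n = config.samples_per_cohort
        samples = [f"{cohort_id}_S{i + 1:03d}" for i in range(n)]

        log_abund = rng_expr.normal(0.0, config.abundance_dispersion, size=(len(cells), n))
        abundance = np.exp(log_abund)

        baseline = rng_expr.normal(7.0, 2.0, size=len(genes))
        expr = np.tile(baseline[:, None], (1, n)) + rng_expr.normal(
            0.0, config.expression_noise_sd, size=(len(genes), n)
        )
        gene_index = {g: i for i, g in enumerate(genes)}
        for ci, cell in enumerate(cells):
            rows = [gene_index[g] for g in assignment[cell]]
            expr[rows, :] += log_abund[ci][None, :]
        # cytolytic effector transcripts track cytotoxic-cell abundance
        if "GZMA" in gene_index and "Activated CD8 T cell" in cells:
            cd8 = log_abund[cells.index("Activated CD8 T cell")]
            expr[gene_index["GZMA"], :] += cd8
            expr[gene_index["PRF1"], :] += cd8

        z = (log_abund - log_abund.mean(axis=1, keepdims=True)) / log_abund.std(
            axis=1, keepdims=True
        )
        lp = gamma @ z  # per-sample log relative hazard

        received = (rng_chemo.random(n) < config.chemo_fraction).astype(int)
        lp_active = lp * received if config.chemo_interaction else lp
        hazard = config.baseline_hazard * np.exp(lp_active)
        t_event = rng_surv.exponential(1.0 / hazard)
        t_cens = rng_surv.exponential(1.0 / config.censoring_rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        expr_df = pd.DataFrame(expr, index=genes, columns=samples)
        surv_df = pd.DataFrame({"sample_id": samples, "time": time, "event": event})
        bundles.append(
            CohortBundle(
                cohort_id=cohort_id,
                expression=ExpressionMatrix(expr_df, scale="log2"),
                survival=SurvivalTable(surv_df),
            )
        )
        abundance_blocks.append(pd.DataFrame(abundance, index=cells, columns=samples))
        lp_blocks.append(pd.Series(lp, index=samples))
        prot = z[protective_mask].mean(axis=0) if protective_mask.any() else np.zeros(n)
        prot_blocks.append(pd.Series(prot, index=samples))
        chemo_blocks.append(pd.Series(received, index=samples))
        cohort_labels.append(pd.Series(cohort_id, index=samples))

    lp_all = pd.concat(lp_blocks)
    truth = SyntheticTruth(
        cell_gene_assignment=assignment,
        latent_abundance=pd.concat(abundance_blocks, axis=1),
        planted_effects=dict(config.planted_effects),
        true_linear_predictor=lp_all,
        protective_lp=-lp_all,
        protective_burden=pd.concat(prot_blocks),
        received_chemo=pd.concat(chemo_blocks),
        cohort_of=pd.concat(cohort_labels),
        seed=config.seed,
    )
    return bundles, truth


def generate_mutations(truth: SyntheticTruth, config: GeneratorConfig) -> MutationTable:
    """Somatic mutation records for every generated sample.

    Coding counts are Poisson with log mean
    ``tmb_log_mean + tmb_coupling * protective_burden``; mutated genes are
    drawn from a fixed frequency list (KRAS the high-frequency driver)
    padded with uniform passenger genes, and a small number of Silent
    records exercise the coding filter.
    """
    burden = truth.protective_burden
    gene_names = list(MUTATION_GENE_FREQS) + [
        f"PSG{i + 1}" for i in range(N_PASSENGER_GENES)
    ]
    driver_p = np.array(list(MUTATION_GENE_FREQS.values()))
    passenger_p = (1.0 - driver_p.sum()) / N_PASSENGER_GENES
    p = np.concatenate([driver_p, np.full(N_PASSENGER_GENES, passenger_p)])

    records = []
    cohorts = truth.cohort_of
    for k, cohort_id in enumerate(pd.unique(cohorts)):
        _, _, rng_mut, _ = _cohort_rngs(config.seed, k)
        for sample in cohorts.index[cohorts == cohort_id]:
            lam = np.exp(config.tmb_log_mean + config.tmb_coupling * burden[sample])
            n_mut = rng_mut.poisson(lam)
            if n_mut > 0:
                muts = rng_mut.choice(gene_names, size=n_mut, p=p)
                vtypes = rng_mut.choice(["SNV", "INS", "DEL"], size=n_mut, p=[0.85, 0.08, 0.07])
                for g, vt in zip(muts, vtypes):
                    vclass = (
                        "Missense_Mutation"
                        if vt == "SNV"
                        else ("Frame_Shift_Ins" if vt == "INS" else "Frame_Shift_Del")
                    )
                    records.append((sample, g, vclass, vt, True))
            n_silent = rng_mut.poisson(2.0)
            for g in rng_mut.choice(gene_names, size=n_silent, p=p):
                records.append((sample, g, "Silent", "SNV", False))
    frame = pd.DataFrame(
        records, columns=["sample_id", "gene", "variant_class", "variant_type", "coding"]
    )
    return MutationTable(frame)


def generate_chemo_labels(truth: SyntheticTruth, config: GeneratorConfig) -> ChemoTable:
    """RECIST response labels; P(CR) logistic in the protective predictor.

    Only patients who received chemotherapy get a response; others are
    ``unknown``.  Non-CR responders split 0.3/0.4/0.3 among PR/SD/PD.
    """
    cohorts = truth.cohort_of
    rows = []
    noncr_cats = list(_NONCR_PROPS)
    noncr_p = np.array(list(_NONCR_PROPS.values()))
    for k, cohort_id in enumerate(pd.unique(cohorts)):
        _, _, _, rng_chemo = _cohort_rngs(config.seed, k)
        rng_resp = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(k, 4)))
        for sample in cohorts.index[cohorts == cohort_id]:
            received = int(truth.received_chemo[sample])
            if received:
                eta = config.chemo_intercept + config.chemo_slope * truth.protective_lp[sample]
                p_cr = 1.0 / (1.0 + np.exp(-eta))
                if rng_resp.random() < p_cr:
                    response = "CR"
                else:
                    response = rng_resp.choice(noncr_cats, p=noncr_p)
            else:
                response = "unknown"
            rows.append((sample, received, response))
    return ChemoTable(pd.DataFrame(rows, columns=["sample_id", "received_chemo", "response"]))


def signature_collection(config: GeneratorConfig) -> GeneSetCollection:
    """The generator's marker-gene blocks as a GMT-style collection."""
    _, assignment = cell_gene_sets(config)
    return GeneSetCollection(
        {cell: list(genes) for cell, genes in assignment.items()},
        descriptions={cell: "synthetic marker block" for cell in assignment},
    )


def generate_dataset(config: GeneratorConfig) -> tuple[list[CohortBundle], SyntheticTruth, GeneSetCollection]:
    """Cohorts with mutation and chemo tables attached, plus truth and GMT."""
    bundles, truth = generate_cohorts(config)
    muts = generate_mutations(truth, config)
    chemo = generate_chemo_labels(truth, config)
    for bundle in bundles:
        samples = set(bundle.expression.sample_ids)
        sub_m = muts.data[muts.data["sample_id"].isin(samples)].reset_index(drop=True)
        bundle.mutations = MutationTable(sub_m)
        sub_c = chemo.data[chemo.data["sample_id"].isin(samples)].reset_index(drop=True)
        bundle.chemo = ChemoTable(sub_c)
    return bundles, truth, signature_collection(config)
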