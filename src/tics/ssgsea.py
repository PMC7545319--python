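"""Single-sample gene set enrichment analysis (ssGSEA).

Scores each gene set in each sample with the rank-based running-sum
statistic: genes are walked in decreasing-rank order; positions inside the
set add ``rank**alpha`` (normalized so the in-set increments sum to 1),
positions outside subtract ``1/(N - |S|)``.  The enrichment score is the
sum of the running difference over all N positions, so the final running
value is exactly zero for every (set, sample) pair.

Because the walk's partial sums telescope, the score has the closed form

    ES = sum_j (N - j + 1) * step_j

with j the 1-based walk position, which is what :func:`ssgsea_matrix`
evaluates as two matrix products (sets x genes) @ (genes x samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentMatrix", "rank_transform", "enrichment_score", "ssgsea_matrix"]


@dataclass
class EnrichmentMatrix:
    """Cell-by-sample enrichment scores plus the scoring parameters."""

    scores: pd.DataFrame  # rows = set names, columns = sample ids
    alpha: float = 0.25
    normalized: bool = True
    min_set_size: int = 5

    @property
    def cell_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def rank_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample ranks of expression, largest value -> largest rank.

    Ties receive the average rank.  A constant column (all ties) is
    permitted and logged.
    """
    values = expr.values
    if values.shape[0] < 2:
        raise ValueError("rank_transform requires at least 2 genes")
    ranks = values.rank(axis=0, method="average")
    constant = values.nunique(axis=0) == 1
    if constant.any():
        logger.info(
            "rank_transform: %d constant sample column(s): %s",
            int(constant.sum()),
            list(values.columns[constant][:5]),
        )
    return ranks


def _walk_order(ranks: np.ndarray, lex_rank: np.ndarray) -> np.ndarray:
    """Positions (0-based) of each gene in the decreasing-rank walk.

    Ties in rank are broken by gene id lexicographic order so the walk is
    deterministic across platforms.
    """
    order = np.lexsort((lex_rank, -ranks))
    pos = np.empty_like(order)
    pos[order] = np.arange(order.size)
    return pos


def enrichment_score(sample_ranks: pd.Series, gene_set: list[str], alpha: float = 0.25) -> float:
    """Enrichment score of one gene set in one sample.

    ``sample_ranks`` maps gene id -> rank (higher = more expressed).  Genes
    in the set but absent from the index are dropped before scoring.
    """
    genes = np.asarray(sample_ranks.index, dtype=object)
    ranks = np.asarray(sample_ranks.values, dtype=float)
    n = genes.size
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has empty intersection with the ranked genes")
    in_set = np.fromiter((g in members for g in genes), dtype=bool, count=n)

    lex_rank = np.empty(n, dtype=np.int64)
    lex_rank[np.argsort(genes)] = np.arange(n)
    pos = _walk_order(ranks, lex_rank)
    coef = (n - pos).astype(float)  # N - j + 1 for 1-based position j

    w = ranks**alpha
    in_num = float(np.sum(coef[in_set] * w[in_set]))
    in_den = float(np.sum(w[in_set]))
    score = in_num / in_den
    n_out = n - int(in_set.sum())
    if n_out > 0:
        score -= float(np.sum(coef[~in_set])) / n_out
    return score


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    min_set_size: int = 5,
) -> EnrichmentMatrix:
    """Score every gene set in every sample.

    Gene symbols are matched case-insensitively between the collection and
    the matrix (exact-case wins on collision).  Sets whose intersection
    with the matrix is smaller than ``min_set_size`` are skipped with a
    warning.  With ``normalize`` the whole matrix is divided by its global
    (max - min) range.
    """
    ranks = rank_transform(expr).to_numpy(dtype=float)
    genes = np.asarray(expr.gene_ids, dtype=object)
    n_genes, n_samples = ranks.shape

    symbol_map = _symbol_lookup(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    usable_names: list[str] = []
    member_cols: list[np.ndarray] = []
    for name, members in sets.items():
        idx = []
        for m in members:
            hit = gene_index.get(m)
            if hit is None:
                hit = symbol_map.get(str(m).upper())
            if hit is not None:
                idx.append(hit)
        idx = sorted(set(idx))
        if len(idx) < min_set_size:
            warnings.warn(
                f"gene set {name!r}: {len(idx)} genes in matrix "
                f"(< min_set_size={min_set_size}); skipped",
                stacklevel=2,
            )
            continue
        col = np.zeros(n_genes, dtype=bool)
        col[idx] = True
        usable_names.append(name)
        member_cols.append(col)
    if not usable_names:
        raise ValueError("no usable gene sets after intersection with the expression matrix")

    membership = np.column_stack(member_cols)  # genes x sets
    sizes = membership.sum(axis=0).astype(float)

    lex_rank = np.empty(n_genes, dtype=np.int64)
    lex_rank[np.argsort(genes)] = np.arange(n_genes)
    coef = np.empty_like(ranks)
    for s in range(n_samples):
        pos = _walk_order(ranks[:, s], lex_rank)
        coef[:, s] = n_genes - pos

    w = ranks**alpha
    in_num = membership.T @ (coef * w)  # sets x samples
    in_den = membership.T @ w
    out_num = coef.sum(axis=0)[None, :] - membership.T @ coef
    n_out = (n_genes - sizes)[:, None]
    scores = in_num / in_den
    nonfull = n_out[:, 0] > 0
    scores[nonfull] -= out_num[nonfull] / n_out[nonfull]

    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
        else:
            logger.warning("ssgsea_matrix: zero score range; normalization skipped")

    frame = pd.DataFrame(scores, index=usable_names, columns=expr.sample_ids)
    return EnrichmentMatrix(frame, alpha=alpha, normalized=normalize, min_set_size=min_set_size)


def _symbol_lookup(genes: np.ndarray) -> dict[str, int]:
    """Uppercase symbol -> row index; exact-case duplicates keep the first."""
    lookup: dict[str, int] = {}
    for i, g in enumerate(genes):
        lookup.setdefault(str(g).upper(), i)
    return lookup
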