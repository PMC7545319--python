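"""Auxiliary scores and comparisons.

Tumor mutational burden (coding mutations per megabase), cytolytic
activity (geometric mean of GZMA and PRF1 on the linear scale), Spearman
association, Benjamini-Hochberg adjustment, group-wise expression
comparison (Wilcoxon rank-sum + BH), and per-gene mutation-frequency
contingency tests between score strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, MutationTable

logger = logging.getLogger(__name__)

__all__ = [
    "TMBResult",
    "CYTResult",
    "compute_tmb",
    "compute_cyt",
    "spearman_assoc",
    "bh_adjust",
    "group_compare",
    "mutation_freq_compare",
]


@dataclass
class TMBResult:
    """Coding mutation counts and mutations-per-megabase per sample."""

    data: pd.DataFrame  # columns: sample_id, count, tmb
    coding_mb: float

    @property
    def tmb(self) -> pd.Series:
        return self.data.set_index("sample_id")["tmb"]


@dataclass
class CYTResult:
    """Cytolytic activity per sample (linear scale)."""

    data: pd.DataFrame  # columns: sample_id, cyt
    offset: float

    @property
    def cyt(self) -> pd.Series:
        return self.data.set_index("sample_id")["cyt"]


def compute_tmb(
    muts: MutationTable, coding_mb: float = 38.0, sample_universe=None
) -> TMBResult:
    """TMB = coding-flagged SNV/INS/DEL count / coding megabases.

    Samples absent from the mutation table get a zero count only when an
    explicit ``sample_universe`` is supplied.
    """
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    coding = muts.data[muts.data["coding"]]
    counts = coding.groupby("sample_id").size()
    if sample_universe is not None:
        counts = counts.reindex(list(sample_universe), fill_value=0)
    frame = pd.DataFrame(
        {"sample_id": counts.index, "count": counts.values, "tmb": counts.values / coding_mb}
    )
    return TMBResult(frame.reset_index(drop=True), coding_mb=coding_mb)


def compute_cyt(
    expr: ExpressionMatrix, offset: float = 0.01, genes: tuple[str, str] = ("GZMA", "PRF1")
) -> CYTResult:
    """Geometric mean of the two cytolytic effector transcripts.

    Computed on the linear scale as sqrt((GZMA + offset) * (PRF1 + offset));
    log2 input is back-transformed first (the scale tag is honored).
    """
    linear = expr.to_linear()
    for g in genes:
        if g not in linear.values.index:
            raise ValueError(f"gene {g!r} not found in expression matrix")
    a = linear.values.loc[genes[0]].to_numpy(dtype=float)
    b = linear.values.loc[genes[1]].to_numpy(dtype=float)
    cyt = np.sqrt((a + offset) * (b + offset))
    frame = pd.DataFrame({"sample_id": linear.sample_ids, "cyt": cyt})
    return CYTResult(frame, offset=offset)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("spearman_assoc requires n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_compare(
    values: pd.DataFrame, groups, min_group: int = 3, test: str = "wilcoxon"
) -> pd.DataFrame:
    """Per-feature two-group comparison with BH adjustment across features.

    ``values`` is features x samples; ``groups`` a binary label per
    sample.  The default test is the two-sided Wilcoxon rank-sum
    (Student's t available via ``test='t'``).  The reported direction is
    the sign of (median group-1 - median group-0).
    """
    g = np.asarray(groups, dtype=int)
    if g.size != values.shape[1]:
        raise ValueError("groups length does not match sample count")
    n1, n0 = int(g.sum()), int((g == 0).sum())
    if min(n0, n1) < min_group:
        raise ValueError(f"both groups must have >= {min_group} samples (got {n0}, {n1})")
    rows = []
    for feature, row in values.iterrows():
        a = row.to_numpy(dtype=float)[g == 1]
        b = row.to_numpy(dtype=float)[g == 0]
        if test == "wilcoxon":
            pooled = np.concatenate([a, b])
            if np.ptp(pooled) == 0:
                stat, p = 0.0, 1.0
            else:
                # exact null when small and tie-free, normal approximation otherwise
                method = (
                    "exact"
                    if pooled.size <= 25 and np.unique(pooled).size == pooled.size
                    else "asymptotic"
                )
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        elif test == "t":
            stat, p = stats.ttest_ind(a, b)
        else:
            raise ValueError(f"test must be 'wilcoxon' or 't', got {test!r}")
        rows.append(
            {
                "feature": feature,
                "statistic": float(stat),
                "p": float(p),
                "direction": float(np.sign(np.median(a) - np.median(b))),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def mutation_freq_compare(
    muts: MutationTable, groups: pd.Series, min_count: int = 3
) -> pd.DataFrame:
    """Per-gene 2x2 mutated/not x high/low contingency tests.

    ``groups`` maps sample_id -> binary stratum label and must cover the
    mutation samples.  Genes mutated in fewer than ``min_count`` samples
    are excluded.  Chi-square with continuity correction is used, falling
    back to Fisher's exact test when any expected cell is below 5; BH is
    applied across the tested genes.
    """
    if muts.data.empty:
        raise ValueError("empty mutation table")
    groups = pd.Series(groups)
    samples = groups.index
    uncovered = set(muts.data["sample_id"]) - set(samples)
    if uncovered:
        raise ValueError(f"groups do not cover mutation sample(s): {sorted(uncovered)[:5]}")
    coding = muts.data[muts.data["coding"]]
    mutated = coding.groupby("gene")["sample_id"].apply(lambda s: set(s))
    n_high = int((groups == 1).sum())
    n_low = int((groups == 0).sum())
    high_samples = set(samples[groups == 1])

    rows = []
    for gene, carriers in mutated.items():
        carriers = carriers & set(samples)
        if len(carriers) < min_count:
            continue
        a = len(carriers & high_samples)  # mutated, high
        b = len(carriers) - a  # mutated, low
        c = n_high - a
        d = n_low - b
        table = np.array([[a, b], [c, d]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            method = "fisher"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            method = "chi2"
        rows.append(
            {
                "gene": gene,
                "mut_high": a,
                "mut_low": b,
                "n_high": n_high,
                "n_low": n_low,
                "odds_ratio": float(odds),
                "p": float(p),
                "method": method,
            }
        )
    if not rows:
        raise ValueError(f"no gene reaches min_count={min_count} mutated samples")
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
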