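"""The TICS construction: per-cohort per-cell Cox, fixed-effects pooling,
prognostic-cell selection, weights, per-sample scores, and stratification.

Each immune cell's enrichment score is median-split within every training
cohort and fit in a univariate Cox model (high vs low).  Per-cell log
hazard ratios are pooled across cohorts by inverse-variance fixed-effects
meta-analysis; cells with pooled p below the selection alpha become the
signature, each weighted

    w_i = (1 - HR_i) / SE(HR_i)

with HR_i the pooled hazard ratio and SE(HR_i) its delta-method standard
error (HR_i * SE(log HR_i)).  Protective cells (HR < 1) therefore get
positive weights and risk cells negative ones.  The per-sample score is
the weighted sum of the cell enrichment scores (Z-standardized per cell
within cohort by default) and is itself Z-normalized within cohort.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortBundle, SurvivalTable
from .ssgsea import EnrichmentMatrix
from .survival import CutoffResult, cox_fit, dichotomize_median, logrank_test, optimal_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "PooledEffect",
    "TICSWeights",
    "TICSScore",
    "per_cohort_cell_cox",
    "pool_fixed_effects",
    "select_prognostic_cells",
    "compute_weights",
    "compute_tics",
    "stratify_tics",
]

COX_TABLE_COLUMNS = [
    "feature", "cohort", "n", "events", "beta", "hr", "se_beta", "se_hr", "z", "p",
]


@dataclass
class PooledEffect:
    """Fixed-effects pooled hazard ratio for one cell across cohorts."""

    cell: str
    k: int
    beta: float
    hr: float
    se_beta: float
    se_hr: float
    z: float
    p: float
    q: float  # Cochran's Q
    i2: float  # I^2 heterogeneity, percent

    @property
    def direction(self) -> str:
        return "risk" if self.hr > 1 else "protective"


@dataclass
class TICSWeights:
    """Frozen (1 - HR)/SE(HR) weights of the selected prognostic cells."""

    weights: dict[str, float]
    alpha: float = 0.05
    se_scale: str = "hr"  # 'hr' (delta-method SE) or 'log' (SE of log HR)
    provenance: dict = field(default_factory=dict)

    @property
    def cells(self) -> list[str]:
        return list(self.weights)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights,
                    "alpha": self.alpha,
                    "se_scale": self.se_scale,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TICSWeights":
        with open(path) as fh:
            payload = json.load(fh)
        if "weights" not in payload or not isinstance(payload["weights"], dict):
            raise ValueError(f"invalid weights artifact: {path}")
        return cls(
            weights={k: float(v) for k, v in payload["weights"].items()},
            alpha=float(payload.get("alpha", 0.05)),
            se_scale=payload.get("se_scale", "hr"),
            provenance=payload.get("provenance", {}),
        )


@dataclass
class TICSScore:
    """Per-sample raw and Z-normalized scores for one cohort."""

    cohort: str
    scores: pd.DataFrame  # columns: sample_id, raw, z
    weights_cells: list[str] = field(default_factory=list)

    @property
    def z(self) -> pd.Series:
        return self.scores.set_index("sample_id")["z"]

    @property
    def raw(self) -> pd.Series:
        return self.scores.set_index("sample_id")["raw"]


def per_cohort_cell_cox(
    cohorts: list[CohortBundle],
    enrichments: list[EnrichmentMatrix],
    ties: str = "efron",
    min_samples: int = 10,
) -> pd.DataFrame:
    """Median-split univariate Cox of every cell in every cohort.

    Returns the full cell x cohort table (non-significant cells included)
    with one row per (cell, cohort); entries where the cell's enrichment
    is constant within a cohort are marked missing (NaN).
    """
    rows = []
    for bundle, enrich in zip(cohorts, enrichments):
        surv = bundle.survival
        samples = [s for s in surv.sample_ids if s in enrich.scores.columns]
        if len(samples) < min_samples:
            warnings.warn(
                f"cohort {bundle.cohort_id}: {len(samples)} usable samples "
                f"(< {min_samples}); excluded from per-cell Cox",
                stacklevel=2,
            )
            continue
        surv_sub = surv.subset(samples)
        sub = enrich.scores.loc[:, surv_sub.sample_ids]
        for cell in enrich.cell_names:
            es = sub.loc[cell].to_numpy(dtype=float)
            row = {"feature": cell, "cohort": bundle.cohort_id}
            try:
                labels = dichotomize_median(es)
                res = cox_fit(
                    surv_sub,
                    labels[:, None].astype(float),
                    ties=ties,
                    feature_names=[cell],
                    cohort=bundle.cohort_id,
                )[0]
                row.update(res.to_dict())
            except ValueError as exc:
                logger.warning("cell %r in cohort %s: %s", cell, bundle.cohort_id, exc)
                row.update(
                    {c: np.nan for c in ("n", "events", "beta", "hr", "se_beta", "se_hr", "z", "p")}
                )
            rows.append(row)
    if not rows:
        raise ValueError("no cohort had enough samples for per-cell Cox")
    return pd.DataFrame(rows)[COX_TABLE_COLUMNS]


def pool_fixed_effects(betas, ses, cell: str = "") -> PooledEffect:
    """Inverse-variance fixed-effects pooling on the log-HR scale.

    ``betas``/``ses`` are per-cohort log hazard ratios and their standard
    errors.  Cochran's Q and I^2 are reported as heterogeneity
    diagnostics.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    keep = np.isfinite(b) & np.isfinite(s)
    b, s = b[keep], s[keep]
    if b.size < 2:
        raise ValueError("fixed-effects pooling requires >= 2 cohort estimates")
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    q = float(np.sum(w * (b - beta) ** 2))
    df = b.size - 1
    i2 = float(max(0.0, (q - df) / q) * 100) if q > 0 else 0.0
    hr = float(np.exp(beta))
    return PooledEffect(
        cell=cell,
        k=int(b.size),
        beta=beta,
        hr=hr,
        se_beta=se,
        se_hr=hr * se,
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        q=q,
        i2=i2,
    )


def pool_cox_table(cox_table: pd.DataFrame) -> list[PooledEffect]:
    """Pool the per-cohort Cox table cell by cell."""
    pooled = []
    for cell, grp in cox_table.groupby("feature", sort=False):
        ok = grp.dropna(subset=["beta", "se_beta"])
        if len(ok) < 2:
            logger.warning("cell %r: <2 cohort estimates; not pooled", cell)
            continue
        pooled.append(pool_fixed_effects(ok["beta"], ok["se_beta"], cell=cell))
    return pooled


def select_prognostic_cells(
    pooled: list[PooledEffect], alpha: float = 0.05, bh: bool = False
) -> list[PooledEffect]:
    """Cells whose pooled effect is significant at ``alpha``, ordered by p.

    With ``bh`` the Benjamini-Hochberg adjusted p is thresholded instead
    of the raw pooled p.
    """
    if not pooled:
        return []
    ps = np.array([e.p for e in pooled])
    if bh:
        from .aux import bh_adjust

        ps = bh_adjust(ps)
    selected = [e for e, p in zip(pooled, ps) if p < alpha]
    return sorted(selected, key=lambda e: e.p)


def compute_weights(
    selected: list[PooledEffect],
    alpha: float = 0.05,
    se_scale: str = "hr",
    provenance: dict | None = None,
) -> TICSWeights:
    """(1 - HR)/SE(HR) weight per selected cell.

    ``se_scale='hr'`` uses the delta-method SE on the hazard-ratio scale
    (the default); ``'log'`` divides by the SE of the log hazard ratio
    instead.
    """
    if not selected:
        raise ValueError("no prognostic cells: cannot compute weights")
    if se_scale not in ("hr", "log"):
        raise ValueError(f"se_scale must be 'hr' or 'log', got {se_scale!r}")
    weights = {}
    for eff in selected:
        se = eff.se_hr if se_scale == "hr" else eff.se_beta
        weights[eff.cell] = (1.0 - eff.hr) / se
    return TICSWeights(
        weights=weights, alpha=alpha, se_scale=se_scale, provenance=provenance or {}
    )


def compute_tics(
    enrich: EnrichmentMatrix,
    weights: TICSWeights,
    cohort: str = "",
    standardize_cells: bool = True,
) -> TICSScore:
    """Weighted sum of cell enrichment scores, Z-normalized within cohort.

    With ``standardize_cells`` each weighted cell's enrichment row is
    Z-standardized within the cohort before weighting (making training
    weights portable across cohorts).
    """
    missing = [c for c in weights.cells if c not in enrich.scores.index]
    if missing:
        raise ValueError(f"enrichment matrix is missing weighted cell(s): {missing}")
    sub = enrich.scores.loc[weights.cells].astype(float)
    if standardize_cells:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            zero = list(sub.index[sd == 0])
            raise ValueError(f"constant enrichment for cell(s) {zero}; cannot standardize")
        sub = sub.sub(mu, axis=0).div(sd, axis=0)
    w = pd.Series(weights.weights)
    raw = sub.mul(w, axis=0).sum(axis=0)
    sd_raw = raw.std(ddof=0)
    z = (raw - raw.mean()) / sd_raw if sd_raw > 0 else raw * 0.0
    frame = pd.DataFrame({"sample_id": raw.index, "raw": raw.values, "z": z.values})
    return TICSScore(cohort=cohort, scores=frame, weights_cells=weights.cells)


def stratify_tics(
    score: TICSScore,
    surv: SurvivalTable,
    minprop: float = 0.1,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, CutoffResult, tuple[float, float]]:
    """High/low split of the cohort at the maximally selected cutpoint.

    Returns (labels indexed by sample id with 1 = high, the cutoff result,
    and the (chi-square, p) of the log-rank test between the strata).
    """
    aligned = score.z.reindex(surv.sample_ids)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()][:5])
        raise ValueError(f"samples missing a TICS score: {missing}")
    cut = optimal_cutoff(
        aligned.to_numpy(), surv, minprop=minprop, n_permutations=n_permutations, rng=rng
    )
    labels = pd.Series(cut.labels, index=surv.sample_ids, name="high_tics")
    lr = logrank_test(surv, cut.labels)
    return labels, cut, lr
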