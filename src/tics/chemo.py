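"""Chemosensitivity analysis.

Score differences by RECIST response category, ROC/AUC for complete
response, logistic two-score combination, and survival contrasts within
and between chemotherapy arms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .io import ChemoTable, SurvivalTable
from .survival import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "roc_auc",
    "compare_response_groups",
    "combine_scores",
    "chemo_survival_contrast",
]

COEF_CAP = 25.0  # |logistic coefficient| flagged as perfect separation


@dataclass
class ROCResult:
    """AUC and the ROC curve it summarizes."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> ROCResult:
    """AUC by the Mann-Whitney pair-counting definition (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels must be paired")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    pos, neg = s[y == 1], s[y == 0]
    conc = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(conc) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, n_pos=n_pos, n_neg=n_neg)


def compare_response_groups(scores: pd.Series, chemo: ChemoTable) -> dict:
    """Score differences across chemotherapy response categories.

    Wilcoxon rank-sum for CR vs non-CR ({PR, SD, PD}) plus Kruskal-Wallis
    across whichever of the four categories are present; ``unknown``
    responses are excluded with a logged count.  ``scores`` is indexed by
    sample id.
    """
    merged = chemo.data.merge(
        scores.rename("score"), left_on="sample_id", right_index=True, how="inner"
    )
    n_unknown = int((merged["response"] == "unknown").sum())
    if n_unknown:
        logger.info("compare_response_groups: excluding %d unknown response(s)", n_unknown)
    merged = merged[merged["response"] != "unknown"]
    if merged.empty:
        raise ValueError("no samples with a known response")

    cr = merged.loc[merged["response"] == "CR", "score"].to_numpy()
    non_cr = merged.loc[merged["response"] != "CR", "score"].to_numpy()
    if cr.size == 0 or non_cr.size == 0:
        raise ValueError("CR vs non-CR comparison requires both classes")
    if min(cr.size, non_cr.size) < 3:
        raise ValueError("CR vs non-CR comparison requires >= 3 samples per group")
    stat, p = stats.mannwhitneyu(cr, non_cr, alternative="two-sided")
    out = {
        "cr_vs_noncr": {
            "statistic": float(stat),
            "p": float(p),
            "median_cr": float(np.median(cr)),
            "median_noncr": float(np.median(non_cr)),
            "n_cr": int(cr.size),
            "n_noncr": int(non_cr.size),
        }
    }
    by_cat = [
        grp["score"].to_numpy()
        for _, grp in merged.groupby("response")
        if len(grp) >= 3
    ]
    if len(by_cat) >= 3:
        kw_stat, kw_p = stats.kruskal(*by_cat)
        out["across_categories"] = {"statistic": float(kw_stat), "p": float(kw_p)}
    return out


def combine_scores(score_a, score_b, labels) -> tuple[np.ndarray, dict]:
    """Logistic combination of two scores for predicting the positive class.

    Both scores are Z-standardized, a two-variable logistic model is fit
    by iteratively reweighted least squares, and the fitted linear
    predictor is the combined score.  The in-sample AUC of the combined
    score is reported alongside each single-score AUC.  Perfect separation
    is flagged and the coefficients capped.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.size == b.size == y.size):
        raise ValueError("scores and labels must be paired")
    if len(np.unique(y)) < 2:
        raise ValueError("combine_scores requires both classes present")

    def _std(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    X = np.column_stack([_std(a), _std(b)])
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = model.coef_[0].copy()
    intercept = float(model.intercept_[0])
    prob = model.predict_proba(X)[:, 1]
    # monotone likelihood: every fitted probability is pinned to its label
    pinned = np.all(np.abs(prob - y) < 1e-3)
    separation = bool(np.abs(coef).max() > COEF_CAP or pinned)
    if separation:
        warnings.warn("perfect separation in logistic combiner; coefficients capped", stacklevel=2)
        coef = np.clip(coef, -COEF_CAP, COEF_CAP)
    combined = X @ coef + intercept
    report = {
        "coef_a": float(coef[0]),
        "coef_b": float(coef[1]),
        "intercept": intercept,
        "separation": separation,
        "auc_combined": roc_auc(combined, y).auc,
        "auc_a": roc_auc(a, y).auc,
        "auc_b": roc_auc(b, y).auc,
    }
    return combined, report


def chemo_survival_contrast(
    strata: pd.Series, surv: SurvivalTable, chemo: ChemoTable
) -> dict:
    """Log-rank contrasts of score strata within each chemotherapy arm.

    ``strata`` maps sample_id -> high/low label.  Reports high-vs-low
    log-rank within received_chemo == 1 and == 0 separately, plus the
    chemo-vs-no-chemo contrast overall.  An empty arm is skipped with a
    warning.
    """
    merged = surv.data.merge(chemo.data[["sample_id", "received_chemo"]], on="sample_id")
    merged = merged.merge(strata.rename("stratum"), left_on="sample_id", right_index=True)
    out: dict = {}
    for arm, key in ((1, "within_chemo"), (0, "within_no_chemo")):
        sub = merged[merged["received_chemo"] == arm]
        if sub.empty:
            warnings.warn(f"empty arm received_chemo={arm}; skipped", stacklevel=2)
            continue
        try:
            table = SurvivalTable(
                sub[["sample_id", "time", "event"]].reset_index(drop=True),
                endpoint=surv.endpoint,
            )
            chi2, p = logrank_test(table, sub["stratum"].to_numpy())
            out[key] = {"chi2": chi2, "p": p, "n": int(len(sub))}
        except ValueError as exc:
            warnings.warn(f"{key}: {exc}", stacklevel=2)
    if merged["received_chemo"].nunique() == 2:
        chi2, p = logrank_test(
            SurvivalTable(
                merged[["sample_id", "time", "event"]].reset_index(drop=True),
                endpoint=surv.endpoint,
            ),
            merged["received_chemo"].to_numpy(),
        )
        out["chemo_vs_no_chemo"] = {"chi2": chi2, "p": p, "n": int(len(merged))}
    return out
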