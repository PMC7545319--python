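"""Core survival statistics.

Kaplan-Meier product-limit estimation, the two-group log-rank test, Cox
proportional-hazards regression (Newton-Raphson on the partial likelihood,
Efron or Breslow ties), median dichotomization, the maximally selected
log-rank cutpoint, time-dependent ROC with inverse-probability-of-censoring
weights, and Harrell's concordance index.

The log-rank statistic is computed by a vectorized routine because the
cutpoint scan and the permutation/calibration suites evaluate it thousands
of times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "CutoffResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "dichotomize_median",
    "optimal_cutoff",
    "time_dependent_auc",
    "concordance_index",
]

#: |beta| beyond which the partial likelihood is treated as monotone
#: (perfect separation); the estimate is capped here with a warning.
BETA_CAP = 15.0


@dataclass
class KMCurve:
    """Product-limit survival curve on the event-time grid."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk at each event time
    n_events: np.ndarray  # events at each event time
    censor_times: np.ndarray  # times of censored observations

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """One Cox coefficient with Wald inference."""

    feature: str
    beta: float
    hr: float
    se_beta: float
    se_hr: float  # delta method: hr * se_beta
    z: float
    p: float
    n: int
    n_events: int
    ties: str
    cohort: str = ""
    converged: bool = True
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "cohort": self.cohort,
            "n": self.n,
            "events": self.n_events,
            "beta": self.beta,
            "hr": self.hr,
            "se_beta": self.se_beta,
            "se_hr": self.se_hr,
            "z": self.z,
            "p": self.p,
        }


@dataclass
class CutoffResult:
    """Maximally selected log-rank threshold on a continuous score."""

    threshold: float
    statistic: float  # |standardized log-rank z| at the threshold
    labels: np.ndarray  # 1 = high (score > threshold)
    minprop: float
    permutation_p: float | None = None


def _check_surv(surv: SurvivalTable) -> tuple[np.ndarray, np.ndarray]:
    t = surv.data["time"].to_numpy(dtype=float)
    d = surv.data["event"].to_numpy(dtype=int)
    if t.size == 0:
        raise ValueError("empty survival table")
    return t, d


def km_estimate(surv: SurvivalTable) -> KMCurve:
    """Kaplan-Meier estimator.

    Censorings at an event time are counted as still at risk at that time.
    With no events the curve is flat at 1 (warned).
    """
    t, d = _check_surv(surv)
    if d.sum() == 0:
        warnings.warn("no events: survival curve is flat at 1", stacklevel=2)
        return KMCurve(
            times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([]),
            n_events=np.array([]),
            censor_times=np.sort(t),
        )
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    event_times = np.unique(ts[ds == 1])
    n = t.size
    at_risk = n - np.searchsorted(ts, event_times, side="left")
    n_events = np.array([int(ds[ts == u].sum()) for u in event_times])
    survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=n_events,
        censor_times=np.sort(t[d == 0]),
    )


def _logrank_z(t: np.ndarray, d: np.ndarray, g: np.ndarray) -> float:
    """Standardized log-rank statistic (O - E)/sqrt(V) for group g == 1.

    Hypergeometric variance at each distinct event time.
    """
    order = np.argsort(t, kind="stable")
    ts, ds, gs = t[order], d[order], g[order]
    ev = ds == 1
    if not ev.any():
        return 0.0
    event_times, first = np.unique(ts[ev], return_index=True)
    # events per distinct time, overall and in group 1
    dj = np.add.reduceat(np.ones(int(ev.sum())), first)
    d1j = np.add.reduceat(gs[ev].astype(float), first)
    # at-risk counts: everyone with ts >= u
    left = np.searchsorted(ts, event_times, side="left")
    nj = ts.size - left
    # suffix count of group-1 members
    suffix1 = np.concatenate([np.cumsum(gs[::-1])[::-1], [0]])
    n1j = suffix1[left]
    expected = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / np.where(nj > 1, nj - 1, 1.0)
    var = np.where(nj > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d1j.sum() - expected.sum()) / np.sqrt(v))


def logrank_test(surv: SurvivalTable, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, two-sided p)."""
    t, d = _check_surv(surv)
    g = np.asarray(groups, dtype=int)
    if g.size != t.size:
        raise ValueError("groups length does not match survival table")
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test requires two nonempty groups")
    if d.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    z = _logrank_z(t, d, g)
    chi2 = z * z
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_derivatives(
    beta: np.ndarray, ts: np.ndarray, ds: np.ndarray, X: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """(log partial likelihood, score, observed information).

    Inputs must be sorted by ascending time.  Risk set of time u is the
    suffix {i : t_i >= u}; tied event times are handled by Efron's or
    Breslow's approximation.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # stabilize exponentials
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix (risk-set) sums, S0[i] = sum_{j>=i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))

    ev_idx = np.flatnonzero(ds == 1)
    if ev_idx.size and np.unique(ts[ev_idx]).size == ev_idx.size:
        # tie-free fast path (Efron == Breslow): fully vectorized
        s0 = S0[ev_idx]
        s1 = S1[ev_idx]
        s2 = S2[ev_idx]
        loglik = float(eta[ev_idx].sum() - np.log(s0).sum())
        ratio = s1 / s0[:, None]
        score = X[ev_idx].sum(axis=0) - ratio.sum(axis=0)
        info = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", ratio, ratio)
        return loglik, score, info

    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        ev = np.arange(i, j)[ds[i:j] == 1]
        m = ev.size
        if m > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            tw, twX = w[ev].sum(), wX[ev].sum(axis=0)
            twXX = wXX[ev].sum(axis=0)
            xsum = X[ev].sum(axis=0)
            loglik += float(eta[ev].sum())
            score += xsum
            if ties == "breslow":
                loglik -= m * np.log(s0)
                score -= m * s1 / s0
                info += m * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:  # efron
                for l in range(m):
                    f = l / m
                    d0 = s0 - f * tw
                    d1 = s1 - f * twX
                    d2 = s2 - f * twXX
                    loglik -= np.log(d0)
                    score -= d1 / d0
                    info += d2 / d0 - np.outer(d1, d1) / d0**2
        i = j
    return loglik, score, info


def _fit_cox(
    t: np.ndarray, d: np.ndarray, X: np.ndarray, ties: str, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Newton-Raphson fit; returns (beta, covariance, converged, separation)."""
    order = np.argsort(t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    separation = False
    loglik_prev = -np.inf
    for _ in range(max_iter):
        loglik, score, info = _cox_derivatives(beta, ts, ds, Xs, ties)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving if the likelihood would decrease
        halvings = 0
        while halvings < 20:
            cand = beta + step
            ll_new, _, _ = _cox_derivatives(cand, ts, ds, Xs, ties)
            if ll_new >= loglik - 1e-12:
                break
            step /= 2.0
            halvings += 1
        beta = beta + step
        if np.abs(beta).max() > BETA_CAP:
            separation = True
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            break
        if np.abs(score).max() < 1e-9 or np.abs(step).max() < 1e-10:
            converged = True
            break
        loglik_prev = loglik
    _, _, info = _cox_derivatives(beta, ts, ds, Xs, ties)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        separation = True
    if separation:
        warnings.warn(
            "monotone partial likelihood (perfect separation); "
            f"coefficients capped at |beta| <= {BETA_CAP}",
            stacklevel=3,
        )
    return beta, cov, converged or separation, separation


def cox_fit(
    surv: SurvivalTable,
    covariates: pd.DataFrame | np.ndarray,
    ties: str = "efron",
    feature_names: list[str] | None = None,
    cohort: str = "",
) -> list[CoxResult]:
    """Cox proportional-hazards regression.

    ``covariates`` is an (n x p) matrix aligned with the survival table
    rows; one :class:`CoxResult` is returned per column (a single-column
    input is a univariate fit).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    t, d = _check_surv(surv)
    if d.sum() < 2:
        raise ValueError("Cox regression requires at least 2 events")
    if isinstance(covariates, pd.DataFrame):
        names = feature_names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and t.size > 1:
            X = X.T
        names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != t.size:
        raise ValueError("covariate rows do not match survival table")
    for k in range(X.shape[1]):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"constant covariate: {names[k]!r}")

    beta, cov, converged, separation = _fit_cox(t, d, X, ties)
    se = np.sqrt(np.diag(cov))
    results = []
    for k, name in enumerate(names):
        b, s = float(beta[k]), float(se[k])
        z = b / s if s > 0 else np.nan
        results.append(
            CoxResult(
                feature=name,
                beta=b,
                hr=float(np.exp(b)),
                se_beta=s,
                se_hr=float(np.exp(b) * s),
                z=z,
                p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                n=int(t.size),
                n_events=int(d.sum()),
                ties=ties,
                cohort=cohort,
                converged=converged,
                separation=separation,
            )
        )
    return results


def cox_score_test(surv: SurvivalTable, covariates, ties: str = "efron") -> tuple[float, float]:
    """Cox score (Rao) test at beta = 0: (chi-square, p).

    On tie-free data with a single binary covariate this is exactly the
    log-rank chi-square.
    """
    t, d = _check_surv(surv)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(t, kind="stable")
    _, score, info = _cox_derivatives(np.zeros(X.shape[1]), t[order], d[order], X[order], ties)
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


# ---------------------------------------------------------------------------
# dichotomization and cutpoint selection


def dichotomize_median(values) -> np.ndarray:
    """1 = above the median, 0 otherwise (ties at the median go low)."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("cannot dichotomize: all values equal")
    return (v > np.median(v)).astype(int)


def optimal_cutoff(
    scores,
    surv: SurvivalTable,
    minprop: float = 0.1,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutoffResult:
    """Maximally selected log-rank cutpoint.

    Scans the midpoints between consecutive sorted unique score values,
    keeps thresholds where both groups hold at least ``minprop`` of the
    samples, and returns the one maximizing the absolute standardized
    log-rank statistic (ties broken toward the median).  If
    ``n_permutations`` > 0, a permutation p-value for the maximal
    statistic is computed by permuting the score vector.
    """
    s = np.asarray(scores, dtype=float)
    t, d = _check_surv(surv)
    if s.size != t.size:
        raise ValueError("scores length does not match survival table")
    if s.size < 10:
        raise ValueError("optimal_cutoff requires >= 10 samples")
    if d.sum() < 2:
        raise ValueError("optimal_cutoff requires >= 2 events")

    uniq = np.unique(s)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n = s.size
    n_min = minprop * n
    admissible = [
        c for c in candidates if min((s > c).sum(), (s <= c).sum()) >= n_min
    ]
    if not admissible:
        raise ValueError(f"no threshold satisfies minprop={minprop}")

    def max_stat(score_vec: np.ndarray) -> tuple[float, float]:
        best_stat, best_thr = -1.0, np.nan
        med = np.median(score_vec)
        for c in admissible:
            g = (score_vec > c).astype(int)
            if 0 < g.sum() < n:
                stat = abs(_logrank_z(t, d, g))
                closer = abs(c - med) < abs(best_thr - med) if np.isfinite(best_thr) else True
                if stat > best_stat + 1e-12 or (abs(stat - best_stat) <= 1e-12 and closer):
                    best_stat, best_thr = stat, c
        return best_stat, best_thr

    obs_stat, obs_thr = max_stat(s)
    perm_p = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        exceed = 0
        for _ in range(n_permutations):
            stat, _ = max_stat(rng.permutation(s))
            if stat >= obs_stat:
                exceed += 1
        perm_p = (1 + exceed) / (1 + n_permutations)
    return CutoffResult(
        threshold=float(obs_thr),
        statistic=float(obs_stat),
        labels=(s > obs_thr).astype(int),
        minprop=minprop,
        permutation_p=perm_p,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC and concordance


def _censoring_survival(t: np.ndarray, d: np.ndarray) -> KMCurve:
    """KM curve of the censoring distribution (censorings are 'events')."""
    table = SurvivalTable(
        pd.DataFrame({"sample_id": [f"s{i}" for i in range(t.size)], "time": t, "event": 1 - d})
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return km_estimate(table)


def time_dependent_auc(scores, surv: SurvivalTable, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW.

    Cases are subjects with an observed event at or before the horizon,
    controls those still under observation beyond it.  Cases are weighted
    by 1/G(t_i-) and controls by 1/G(horizon), G the Kaplan-Meier
    estimate of the censoring survival.  Without censoring this equals the
    plain ROC AUC of the binary label "event <= horizon".
    """
    s = np.asarray(scores, dtype=float)
    t, d = _check_surv(surv)
    case = (t <= horizon) & (d == 1)
    control = t > horizon
    if not case.any() or not control.any():
        raise ValueError("time_dependent_auc: need >= 1 event before and >= 1 survivor past t")

    G = _censoring_survival(t, d)
    # G(t-): left limit just before each case's event time
    w_case = np.array([1.0 / max(G.survival_at(ti - 1e-12), 1e-12) for ti in t[case]])
    # control weight 1/G(horizon) is constant and cancels in the ratio
    sc, ss = s[case], s[control]
    greater = (sc[:, None] < ss[None, :]).astype(float)  # control outranks case? no:
    # case should have HIGHER score than control for a risk score
    conc = (sc[:, None] > ss[None, :]).astype(float) + 0.5 * (sc[:, None] == ss[None, :])
    num = float((w_case[:, None] * conc).sum())
    den = float(w_case.sum() * ss.size)
    return num / den


def concordance_index(surv: SurvivalTable, scores) -> float:
    """Harrell's C: agreement of higher score with longer survival.

    Pairs are comparable when the shorter time is an observed event; tied
    scores count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t, d = _check_surv(surv)
    conc = 0.0
    n_pairs = 0
    for i in range(t.size):
        if d[i] != 1:
            continue
        comparable = t > t[i]
        n = int(comparable.sum())
        if n == 0:
            continue
        n_pairs += n
        conc += float((s[comparable] > s[i]).sum()) + 0.5 * float((s[comparable] == s[i]).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return conc / n_pairs
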