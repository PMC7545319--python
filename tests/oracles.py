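"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal route available
(explicit walks, grid search, enumeration) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_ssgsea_score(values: dict[str, float], gene_set: set[str], alpha: float) -> float:
    """Explicit running-sum ssGSEA score for one sample.

    ``values`` maps gene id -> expression.  Ranks are average-tie ranks of
    the expression values (largest value, largest rank); the walk visits
    genes in decreasing rank, ties broken by lexicographic gene id; the
    score is the sum of the running difference after each step.
    """
    genes = list(values)
    n = len(genes)
    # average-tie ranks, computed longhand
    ranks: dict[str, float] = {}
    for g in genes:
        less = sum(1 for h in genes if values[h] < values[g])
        equal = sum(1 for h in genes if values[h] == values[g])
        ranks[g] = less + (equal + 1) / 2.0
    walk = sorted(genes, key=lambda g: (-ranks[g], g))
    in_set = [g in gene_set for g in walk]
    denom_in = sum(ranks[g] ** alpha for g, flag in zip(walk, in_set) if flag)
    n_out = n - sum(in_set)
    running = 0.0
    total = 0.0
    for g, flag in zip(walk, in_set):
        if flag:
            running += ranks[g] ** alpha / denom_in
        else:
            running -= 1.0 / n_out
        total += running
    return total


def naive_ssgsea_final_running_value(
    values: dict[str, float], gene_set: set[str], alpha: float
) -> float:
    """Final running-sum value after the full walk (should be 0)."""
    genes = list(values)
    n = len(genes)
    ranks: dict[str, float] = {}
    for g in genes:
        less = sum(1 for h in genes if values[h] < values[g])
        equal = sum(1 for h in genes if values[h] == values[g])
        ranks[g] = less + (equal + 1) / 2.0
    walk = sorted(genes, key=lambda g: (-ranks[g], g))
    in_set = [g in gene_set for g in walk]
    denom_in = sum(ranks[g] ** alpha for g, flag in zip(walk, in_set) if flag)
    n_out = n - sum(in_set)
    running = 0.0
    for g, flag in zip(walk, in_set):
        running += ranks[g] ** alpha / denom_in if flag else -1.0 / n_out
    return running


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Literal tie-free Cox partial log-likelihood for one covariate."""
    total = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        total += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return total


def cox_grid_search(times, events, x, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Maximize the partial likelihood over a beta grid."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def wilcoxon_exact_p(a, b) -> float:
    """Exact two-sided Wilcoxon rank-sum p by enumerating all splits."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {}
    srt = sorted(pooled)
    for v in set(pooled):
        pos = [i + 1 for i, w in enumerate(srt) if w == v]
        ranks[v] = sum(pos) / len(pos)
    obs = sum(ranks[v] for v in a)
    mean_r = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        stat = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(stat - mean_r) >= abs(obs - mean_r) - 1e-12:
            count += 1
    return count / total


def hypergeom_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] from the
    hypergeometric pmf, summing tables as or less probable."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic, counted pair by pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            u += 1.0 if p > q else (0.5 if p == q else 0.0)
    return u / (len(pos) * len(neg))
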