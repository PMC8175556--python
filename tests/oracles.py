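"""Independent brute-force oracles used by the test suite.

Each oracle is written against the definition of the statistic, not against
the library code path it checks: Fisher's exact P by hypergeometric
enumeration, the Mann-Whitney two-sided P by enumerating label assignments,
BH by an explicit step-up loop, pathway scores by a two-pass loop, and DRS by
a two-loop weighted sum.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P: sum hypergeometric probabilities <= observed's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_prob(x))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def mwu_p_enumeration(x, y) -> float:
    """Exact two-sided Mann-Whitney P by enumerating all label assignments."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}  # no ties assumed

    def u_of(subset) -> float:
        r = sum(ranks[v] for v in subset)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(x)
    u_lo = min(u_obs, n1 * n2 - u_obs)
    u_hi = n1 * n2 - u_lo
    count = 0
    total = 0
    for subset in itertools.combinations(combined, n1):
        u = u_of(subset)
        if u <= u_lo + 1e-12 or u >= u_hi - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_stepup_loop(p) -> np.ndarray:
    """BH step-up with explicit loops: q_(i) = min_{j>=i} m p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        best = math.inf
        for j_pos in range(rank_pos, m + 1):
            pj = p[order[j_pos - 1]]
            best = min(best, m * pj / j_pos)
        q[idx] = min(best, 1.0)
    return q


def pathway_score_loops(expr_values, gene_idx):
    """Two-pass pathway score: z-score rows with ddof=1, then column means."""
    sub = np.asarray(expr_values, dtype=float)[list(gene_idx), :]
    n_genes, n_samples = sub.shape
    z = np.empty_like(sub)
    for g in range(n_genes):
        mu = sub[g].mean()
        sd = sub[g].std(ddof=1)
        z[g] = (sub[g] - mu) / sd if sd > 0 else 0.0
    return np.array([z[:, s].mean() for s in range(n_samples)])


def drs_loops(expr_values, gene_rows, cors):
    """Two-loop DRS: sum(cor * x) / sum(cor) per sample."""
    expr_values = np.asarray(expr_values, dtype=float)
    n_samples = expr_values.shape[1]
    out = np.empty(n_samples)
    for s in range(n_samples):
        num = 0.0
        den = 0.0
        for row, cor in zip(gene_rows, cors):
            num += cor * expr_values[row, s]
            den += cor
        out[s] = num / den
    return out


def logit_beta_2x2(n11: int, n10: int, n01: int, n00: int) -> float:
    """Closed-form saturated logistic coefficient: log odds ratio of a 2x2.

    Cells are counts of (y, x) pairs: n_yx.
    """
    return math.log((n11 * n00) / (n10 * n01))
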