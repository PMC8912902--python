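"""Nonparametric tests used throughout the workflow.

qPCR group sizes here are small (typically 6-8 samples per group), so the
Mann-Whitney U test uses the exact permutation distribution whenever the
combined sample size allows it; ties are handled with mid-ranks and the
permutation distribution of the mid-rank U.  The Kruskal-Wallis H statistic
and Dunn's control-versus-others post test carry the standard tie
corrections; the chi-square tail and the large-sample Mann-Whitney branch
are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

#: largest combined sample size for which the exact permutation
#: distribution of U is enumerated (C(20,10) = 184756 assignments).
EXACT_MW_MAX_N = 20


def mann_whitney_exact(x, y, exact_max_n: int = EXACT_MW_MAX_N) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact for small samples.

    Returns ``(U, p)`` where U counts pairs with x above y (ties count
    one half).  For combined n <= ``exact_max_n`` the p-value enumerates
    every C(N, n1) assignment of the pooled mid-ranks to the first group:
    p = min(1, 2 * min(P(U <= u), P(U >= u))).  Larger samples fall back
    to the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n > exact_max_n:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return u_obs, float(res.pvalue)
    offset = n1 * (n1 + 1) / 2.0
    total = comb(n, n1)
    # enumerate rank sums of every subset of size n1
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for subset in combinations(ranks, n1):
        u = sum(subset) - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return u_obs, float(min(1.0, p))


def kruskal_wallis(samples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    ``samples`` is a sequence of >= 2 groups of >= 2 real values.  H is
    computed from pooled mid-ranks and divided by the tie-correction
    factor 1 - sum(t^3 - t)/(N^3 - N).  All-identical input returns
    (0, 1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n**3 - n)
    if denom <= 0:  # every value identical
        return 0.0, 1.0
    h_c = h / denom
    df = len(groups) - 1
    p = float(sps.chi2.sf(h_c, df))
    return float(h_c), p


@dataclass
class DunnComparison:
    comparison: str
    z: float
    p_raw: float
    p_adjusted: float


def dunns_posthoc(samples, control: int = 0, adjust: str = "bonferroni",
                  labels=None) -> pd.DataFrame:
    """Dunn's rank-based post test, control versus each other group.

    Uses pooled mid-ranks from all groups; for each non-control group j,
    z = (Rbar_c - Rbar_j) / sqrt(V * (1/n_c + 1/n_j)) with
    V = N(N+1)/12 - sum(t^3 - t)/(12(N-1)).  Two-sided normal p-values
    are adjusted over the (G - 1) planned comparisons (bonferroni, sidak,
    or none).
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    g_count = len(groups)
    if not (0 <= control < g_count):
        raise ValueError(f"control index {control} out of range for {g_count} groups")
    if labels is None:
        labels = [f"group{i}" for i in range(g_count)]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    variance = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    m = g_count - 1
    rows = []
    for j in range(g_count):
        if j == control:
            continue
        se = np.sqrt(variance * (1.0 / groups[control].size + 1.0 / groups[j].size))
        z = (mean_ranks[control] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p_adj = min(1.0, m * p_raw)
        elif adjust == "sidak":
            p_adj = 1.0 - (1.0 - p_raw) ** m
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append(DunnComparison(
            comparison=f"{labels[control]} vs {labels[j]}",
            z=float(z), p_raw=p_raw, p_adjusted=float(p_adj),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
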