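"""Nonparametric test primitives: Kruskal-Wallis, Mann-Whitney, exact
prevalence (Fisher) tests and Benjamini-Hochberg adjustment.

These wrap scipy where scipy implements the test, and add the behaviours
the pipeline needs on top: missing-value handling, degenerate-input
conventions, an exact 2xk prevalence test (scipy only covers 2x2), and BH
adjustment that passes missing p-values through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import scipy.stats as sps


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    Missing values are dropped per group; groups left empty are excluded.
    All-identical data give the degenerate (H=0, p=1).
    """
    cleaned = [_clean(g) for g in groups]
    cleaned = [g for g in cleaned if len(g) > 0]
    if len(cleaned) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    return float(h), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when min(n_a, n_b) <= 8 and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    """
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney needs non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FisherResult:
    p: float
    method: str  # "exact-2x2" | "exact-2xk" | "monte-carlo"
    se: float | None = None  # standard error of the Monte-Carlo estimate


def _table_prob(x: np.ndarray, sizes: np.ndarray, denom: float) -> float:
    prob = 1.0
    for xi, ni in zip(x, sizes):
        prob *= comb(int(ni), int(xi))
    return prob / denom


def fisher_prevalence(
    positives, sizes, seed: int = 0, mc_draws: int = 100_000, exact_n_max: int = 40
) -> FisherResult:
    """Exact test of equal prevalence across groups.

    ``positives[g]`` is the number of detected samples in group g out of
    ``sizes[g]``.  For 2 groups this is the classic two-sided Fisher exact
    test; for k > 2 groups the 2xk table is tested exactly by enumerating
    all tables with the observed margins (multivariate hypergeometric) when
    the total sample count is <= ``exact_n_max``, and by Monte-Carlo
    otherwise (p-value standard error reported).  Two-sidedness is by
    summation of all table probabilities <= the observed one.
    """
    positives = np.asarray(positives, dtype=int)
    sizes = np.asarray(sizes, dtype=int)
    if len(positives) < 2:
        raise ValueError("prevalence test needs >= 2 groups")
    if (positives > sizes).any() or (positives < 0).any():
        raise ValueError("positives must lie in [0, group size]")
    if len(positives) == 2:
        table = np.array([positives, sizes - positives])
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return FisherResult(p=float(min(p, 1.0)), method="exact-2x2")

    m, n_total = int(positives.sum()), int(sizes.sum())
    denom = comb(n_total, m)
    p_obs = _table_prob(positives, sizes, denom)
    cutoff = p_obs * (1 + 1e-7)  # guard against float round-off at equality

    if n_total <= exact_n_max:
        k = len(sizes)

        def rec(g: int, remaining: int, prob: float) -> float:
            if g == k - 1:
                if 0 <= remaining <= sizes[g]:
                    return prob * comb(int(sizes[g]), remaining) if (
                        prob * comb(int(sizes[g]), remaining) / denom <= cutoff
                    ) else 0.0
                return 0.0
            total = 0.0
            lo = max(0, remaining - int(sizes[g + 1:].sum()))
            hi = min(int(sizes[g]), remaining)
            for x in range(lo, hi + 1):
                total += rec(g + 1, remaining - x, prob * comb(int(sizes[g]), x))
            return total

        p = rec(0, m, 1.0) / denom
        return FisherResult(p=float(min(p, 1.0)), method="exact-2xk")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(sizes, m, size=mc_draws)
    from scipy.special import gammaln

    def log_prob(x):
        return (
            gammaln(sizes + 1).sum(axis=-1)
            - gammaln(x + 1).sum(axis=-1)
            - gammaln(sizes - x + 1).sum(axis=-1)
        )

    lp_obs = log_prob(positives[None, :])[0]
    lp = log_prob(draws)
    hits = (lp <= lp_obs + 1e-9).mean()
    se = float(np.sqrt(hits * (1 - hits) / mc_draws))
    return FisherResult(p=float(max(hits, 1 / mc_draws)), method="monte-carlo", se=se)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with missing pass-through.

    Missing (NaN) entries stay missing and do not count toward m, the
    number of tests.  Output is capped at 1 and is elementwise >= input.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[mask] = unsorted
    return out
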