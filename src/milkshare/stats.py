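"""Shared statistical primitives: exact Fisher test, BH step-up, Dunn post hoc."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float  # a*d/(b*c); inf when b*c == 0 and a*d > 0; nan for 0/0


# relative tolerance used when comparing hypergeometric point probabilities,
# the convention of the common exact-test implementations
_FISHER_REL_TOL = 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    With both margins fixed, the two-sided p-value sums the hypergeometric
    probabilities of every table whose point probability does not exceed the
    observed one (up to a 1e-7 relative tolerance). The point probabilities
    are computed with exact integer weights, so ties are resolved exactly.
    The odds ratio is the unconditional sample estimate ``a*d/(b*c)`` with
    inf/0 sentinels; an all-zero table has p = 1 and an undefined odds ratio.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return FisherResult(p=1.0, odds_ratio=math.nan)
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer hypergeometric weights: w(x) = C(r1, x) * C(r2, c1 - x)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    # threshold w <= w_obs * (1 + tol), evaluated in exact integer arithmetic
    scale = 10**9
    thresh = w_obs * (scale + int(_FISHER_REL_TOL * scale)) // scale
    num = sum(w for w in weights if w <= thresh)
    p = num / sum(weights)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return FisherResult(p=min(1.0, p), odds_ratio=odds)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on joint ranks after a Kruskal-Wallis test.

    Uses the tie-corrected pooled variance; two-sided normal p-values are BH
    adjusted across all pairwise comparisons (one family per omnibus test).
    Returns a tidy frame with columns group_a, group_b, z, p, fdr.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = math.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": gi, "group_b": gj, "z": z, "p": min(1.0, p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
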