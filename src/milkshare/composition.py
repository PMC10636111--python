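"""Compositional analysis of genus-level amplicon profiles.

Counts are aggregated to genus level, closed to relative abundances,
centred-log-ratio (CLR) transformed and compared in Aitchison geometry:
Euclidean distances between CLR rows feed ordination (PCoA), hierarchical
clustering, and a multi-factor permutational MANOVA (PERMANOVA) with
sequential sums of squares. Per-genus linear models with sample fixed
effects quantify method shifts on the CLR scale, and classical group tests
(Kruskal-Wallis/Dunn, Mann-Whitney, Spearman, Fisher) cover the scalar
per-sample summaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .datamodel import (
    AsvTable,
    DistanceMatrix,
    MockReference,
    UNCLASSIFIED,
    round_half_away,
)
from .stats import bh_adjust, dunn_posthoc, fisher_exact_2x2

OTHER_UNCLASSIFIED = "OTHER_UNCLASSIFIED"


# ---------------------------------------------------------------------------
# genus aggregation


@dataclass
class GenusTable:
    """Genus-level counts and relative abundances (rows = samples).

    ``closure`` records whether relative abundances are closed over all
    retained reads (``"all"``, genus-unclassified reads pooled into
    OTHER_UNCLASSIFIED) or over classified-genus reads only
    (``"classified"``). Samples with zero total reads keep an all-zero row
    and are listed in ``zero_samples`` rather than being renormalized.
    """

    counts: pd.DataFrame
    rel: pd.DataFrame
    zero_samples: list[str]
    closure: str = "all"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    def drop_zero_samples(self) -> "GenusTable":
        keep = [s for s in self.sample_ids if s not in self.zero_samples]
        return GenusTable(
            self.counts.loc[keep], self.rel.loc[keep], [], closure=self.closure
        )


def genus_aggregate(
    table: AsvTable, taxonomy: pd.DataFrame, closure: str = "all"
) -> GenusTable:
    """Sum ASV counts per genus and close to relative abundances.

    ASVs without genus-level classification are pooled into a single
    OTHER_UNCLASSIFIED column; with ``closure="classified"`` that column is
    dropped before closure so fractions are over classified reads only.
    """
    if closure not in ("all", "classified"):
        raise ValueError(f"unknown closure {closure!r}")
    missing = [a for a in table.asv_ids if a not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing for ASVs: {missing[:5]}...")
    genus = taxonomy.loc[table.asv_ids, "genus"].replace(
        UNCLASSIFIED, OTHER_UNCLASSIFIED
    )
    counts = table.counts.T.groupby(genus.values).sum().T
    counts = counts[sorted(counts.columns)]
    if closure == "classified" and OTHER_UNCLASSIFIED in counts.columns:
        counts = counts.drop(columns=OTHER_UNCLASSIFIED)
    totals = counts.sum(axis=1)
    zero_samples = list(totals.index[totals == 0])
    if zero_samples:
        warnings.warn(
            f"samples with zero retained reads excluded from closure: {zero_samples}",
            stacklevel=2,
        )
    rel = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return GenusTable(counts=counts, rel=rel, zero_samples=zero_samples, closure=closure)


# ---------------------------------------------------------------------------
# CLR and Aitchison geometry


def clr_transform(
    data: "GenusTable | pd.DataFrame | np.ndarray", pseudocount: float | None = None
) -> pd.DataFrame:
    """Centred log-ratio transform, row-wise: ln(x_ij / g(x_i)).

    For a :class:`GenusTable` the pseudocount (default 0.5) is added to the
    genus *counts* before closure, the standard count-zero treatment. For a
    raw composition matrix the default pseudocount is 0; zeros then raise.
    Every output row sums to zero.
    """
    if isinstance(data, GenusTable):
        pc = 0.5 if pseudocount is None else pseudocount
        gt = data.drop_zero_samples()
        x = gt.counts.to_numpy(dtype=float) + pc
        index, columns = gt.counts.index, gt.counts.columns
    else:
        pc = 0.0 if pseudocount is None else pseudocount
        if isinstance(data, pd.DataFrame):
            x = data.to_numpy(dtype=float) + pc
            index, columns = data.index, data.columns
        else:
            x = np.asarray(data, dtype=float) + pc
            if x.ndim == 1:
                x = x[None, :]
            index = pd.RangeIndex(x.shape[0])
            columns = pd.RangeIndex(x.shape[1])
    if np.any(x <= 0):
        raise ValueError(
            "non-positive values in composition; use a positive pseudocount"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=index, columns=columns)


def aitchison_distances(
    clr: "pd.DataFrame | np.ndarray", labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Euclidean distances between CLR rows (the Aitchison metric)."""
    if isinstance(clr, pd.DataFrame):
        labels = list(clr.index) if labels is None else list(labels)
        arr = clr.to_numpy(dtype=float)
    else:
        arr = np.asarray(clr, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])] if labels is None else list(labels)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries in CLR matrix")
    return DistanceMatrix(labels, squareform(pdist(arr, metric="euclidean")))


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    """Classical multidimensional scaling of a distance matrix (Gower, 1966)."""

    coordinates: pd.DataFrame          # samples x retained (positive) axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over the positive eigenvalues only

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-9) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    Eigendecomposes ``-0.5 * J D^2 J``; axes are ordered by decreasing
    eigenvalue and scaled by the square root of the eigenvalue. Negative
    eigenvalues (non-Euclidean input) are reported, never clipped silently;
    only axes with eigenvalue > ``eig_tol`` carry coordinates.
    """
    if d.n < 2:
        raise ValueError("PCoA needs at least two samples")
    n = d.n
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > eig_tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PCo{i + 1}" for i in range(pos.sum())]
    prop = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.labels, columns=axes),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA (sequential sums of squares, adonis-style)


@dataclass
class PermanovaResult:
    """Term table of a PERMANOVA fit; r2 entries sum to 1 with the residual."""

    table: pd.DataFrame                # term, df, ss, r2, pseudo_f, p
    n_permutations: int
    seed: int | None
    skipped_terms: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.table

    def r2(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "r2"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


class Permanova:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squares of ``distance_matrix`` among the
    factors in the given order (sequential, type-I), computing a pseudo-F
    per term and permutation p-values under unrestricted whole-row label
    permutation: p = (1 + #{F* >= F}) / (1 + n_permutations). With
    ``exhaustive=True`` every permutation is enumerated instead (p is then
    the exact fraction, observed permutation included).
    """

    def __init__(
        self,
        distance_matrix: DistanceMatrix,
        factors: Mapping[str, Sequence],
        n_permutations: int = 999,
        seed: int | None = None,
        exhaustive: bool = False,
    ):
        self.d = distance_matrix
        self.factors = {k: list(v) for k, v in factors.items()}
        for name, labels in self.factors.items():
            if len(labels) != distance_matrix.n:
                raise ValueError(f"factor {name!r} does not cover all samples")
        self.n_permutations = n_permutations
        self.seed = seed
        self.exhaustive = exhaustive

    def _design_blocks(self) -> tuple[list[str], list[np.ndarray], list[str]]:
        names, blocks, skipped = [], [], []
        for name, labels in self.factors.items():
            levels = pd.unique(pd.Series(labels))
            if len(levels) < 2:
                warnings.warn(f"factor {name!r} has a single level; term skipped", stacklevel=2)
                skipped.append(name)
                continue
            names.append(name)
            blocks.append(pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float))
        return names, blocks, skipped

    def fit(self) -> PermanovaResult:
        n = self.d.n
        a = -0.5 * self.d.values**2
        j = np.eye(n) - np.ones((n, n)) / n
        g = j @ a @ j
        ss_total = float(np.trace(g))

        names, blocks, skipped = self._design_blocks()
        if not names:
            raise ValueError("no usable factors (all single-level)")

        # cumulative hat matrices: intercept, then one per added term
        hats = [np.ones((n, n)) / n]
        ranks = [1]
        x = np.ones((n, 1))
        kept_names = []
        for name, b in zip(names, blocks):
            xb = np.hstack([x, b])
            # SVD-based projector: robust to the rank deficiency of dummy coding
            u, s, _ = np.linalg.svd(xb, full_matrices=False)
            keep = s > s[0] * 1e-10
            rank = int(keep.sum())
            if rank == ranks[-1]:
                warnings.warn(
                    f"factor {name!r} is collinear with earlier terms; term skipped",
                    stacklevel=2,
                )
                skipped.append(name)
                continue
            x = xb
            hats.append(u[:, keep] @ u[:, keep].T)
            ranks.append(rank)
            kept_names.append(name)
        names = kept_names
        if not names:
            raise ValueError("no usable factors after collinearity checks")
        dfs = np.diff(ranks)
        df_res = n - ranks[-1]
        if df_res <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")

        def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
            traces = np.array([float(np.sum(h * gmat)) for h in hats])
            ss_terms = np.diff(traces)
            ss_res = float(np.trace(gmat)) - traces[-1]
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss_terms / dfs) / (ss_res / df_res)  # inf when ss_res == 0
            return ss_terms, f

        ss_obs, f_obs = term_stats(g)
        ss_res_obs = ss_total - ss_obs.sum()

        tol = 1e-12
        if self.exhaustive:
            perms = list(itertools.permutations(range(n)))
            count = np.zeros(len(names))
            for perm in perms:
                idx = np.asarray(perm)
                _, f_perm = term_stats(g[np.ix_(idx, idx)])
                count += f_perm >= f_obs - tol
            pvals = count / len(perms)
            n_perm_used = len(perms)
        else:
            rng = np.random.default_rng(self.seed)
            count = np.zeros(len(names))
            for _ in range(self.n_permutations):
                idx = rng.permutation(n)
                _, f_perm = term_stats(g[np.ix_(idx, idx)])
                count += f_perm >= f_obs - tol
            pvals = (1.0 + count) / (1.0 + self.n_permutations)
            n_perm_used = self.n_permutations

        rows = [
            {
                "term": name,
                "df": int(dfs[k]),
                "ss": ss_obs[k],
                "r2": ss_obs[k] / ss_total,
                "pseudo_f": f_obs[k],
                "p": pvals[k],
            }
            for k, name in enumerate(names)
        ]
        rows.append(
            {
                "term": "Residual",
                "df": df_res,
                "ss": ss_res_obs,
                "r2": ss_res_obs / ss_total,
                "pseudo_f": np.nan,
                "p": np.nan,
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": n - 1,
                "ss": ss_total,
                "r2": 1.0,
                "pseudo_f": np.nan,
                "p": np.nan,
            }
        )
        return PermanovaResult(
            table=pd.DataFrame(rows),
            n_permutations=n_perm_used,
            seed=self.seed,
            skipped_terms=skipped,
        )


def permanova(
    d: DistanceMatrix,
    factors: Mapping[str, Sequence],
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(d, factors, n_permutations, seed, exhaustive).fit()


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray    # scipy linkage encoding of the merge list
    leaf_order: list[str]
    method: str

    def cophenetic(self) -> DistanceMatrix:
        coph = sch.cophenet(self.linkage_matrix)
        return DistanceMatrix(self.labels, squareform(coph))


def hclust_order(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix (default average linkage).

    Ties are broken deterministically by the input label order (scipy's
    stable merge order for equal heights).
    """
    if d.n < 2:
        raise ValueError("clustering needs at least two samples")
    z = sch.linkage(squareform(d.values, checks=False), method=linkage)
    order = [d.labels[i] for i in sch.leaves_list(z)]
    return Dendrogram(labels=d.labels, linkage_matrix=z, leaf_order=order, method=linkage)


# ---------------------------------------------------------------------------
# mock-community evaluation


@dataclass
class MockEvaluation:
    detected: list[str]
    missing: list[str]
    unexpected: list[str]
    trace_unexpected: list[str]      # unexpected below the trace threshold
    log_ratio_bias: pd.Series        # ln(observed / expected) per detected expected genus
    aitchison_distance: float


def evaluate_mock(
    observed: pd.Series,
    reference: MockReference,
    trace_threshold: float = 2e-4,
    zero_replacement: float = 1e-6,
) -> MockEvaluation:
    """Compare one genus-level mock profile to its theoretical reference.

    Lists expected genera that were detected or missed and unexpected genera
    (those below ``trace_threshold`` relative abundance flagged as trace),
    the per-genus log-ratio bias, and the Aitchison distance to the
    reference over the union of genera (zeros replaced multiplicatively).
    """
    obs = observed[observed > 0]
    obs = obs / observed.sum() if observed.sum() > 0 else obs
    expected = reference.as_series()
    detected = [g for g in reference.genera if g in obs.index]
    missing = [g for g in reference.genera if g not in obs.index]
    unexpected = [g for g in obs.index if g not in reference.genera]
    trace = [g for g in unexpected if obs[g] < trace_threshold]
    bias = pd.Series(
        {g: math.log(obs[g] / expected[g]) for g in detected if expected[g] > 0},
        dtype=float,
    )
    union = sorted(set(obs.index) | set(reference.genera))
    o = np.array([obs.get(g, 0.0) for g in union])
    e = np.array([expected.get(g, 0.0) for g in union])
    o = np.where(o == 0, zero_replacement, o)
    e = np.where(e == 0, zero_replacement, e)
    clr_pair = clr_transform(np.vstack([o / o.sum(), e / e.sum()]))
    dist = float(np.linalg.norm(clr_pair.iloc[0] - clr_pair.iloc[1]))
    return MockEvaluation(detected, missing, unexpected, trace, bias, dist)


# ---------------------------------------------------------------------------
# prevalence / abundance summaries


def core_genera(
    g: GenusTable, prevalence_threshold: float = 0.7, sample_ids: Sequence[str] | None = None
) -> list[str]:
    """Genera detected (abundance > 0) in at least the given fraction of samples."""
    if not (0 < prevalence_threshold <= 1):
        raise ValueError("prevalence_threshold must be in (0, 1]")
    rel = g.rel if sample_ids is None else g.rel.loc[list(sample_ids)]
    prevalence = (rel > 0).mean(axis=0)
    return sorted(prevalence.index[prevalence >= prevalence_threshold])


@dataclass
class DisplayFilter:
    retained: list[str]
    other: list[str]
    dominant: list[str]              # >= dominant_abund in at least one sample
    filtered_rel: pd.DataFrame       # retained genera plus a summed "Other" column


def display_filter(
    g: GenusTable,
    min_samples: int = 2,
    min_abund: float = 0.02,
    dominant_abund: float = 0.15,
) -> DisplayFilter:
    """Panel display rule: keep genera present in >= ``min_samples`` samples
    that reach >= ``min_abund`` relative abundance in at least one sample;
    everything else (including unclassified reads) sums into "Other".
    Dominant genera additionally satisfy the >= ``dominant_abund`` rule."""
    rel = g.rel
    present_in = (rel > 0).sum(axis=0)
    reaches = (rel >= min_abund).any(axis=0)
    keep = (present_in >= min_samples) & reaches
    if OTHER_UNCLASSIFIED in keep.index:
        keep[OTHER_UNCLASSIFIED] = False  # unclassified reads always go to Other
    retained = sorted(keep.index[keep])
    other = sorted(keep.index[~keep])
    dominant = sorted(rel.columns[(rel >= dominant_abund).any(axis=0) & keep])
    out = rel[retained].copy()
    out["Other"] = rel[other].sum(axis=1)
    return DisplayFilter(retained, other, dominant, out)


# ---------------------------------------------------------------------------
# per-genus CLR linear models


@dataclass
class ClrGenusModelsResult:
    table: pd.DataFrame              # genus, coef per non-reference level, p, fdr

    def summary(self) -> pd.DataFrame:
        return self.table

    def significant(self, alpha: float = 0.05) -> list[str]:
        return sorted(self.table.loc[self.table["fdr"] < alpha, "genus"])


class ClrGenusModels:
    """OLS of CLR abundance per genus on a factor of interest plus fixed effects.

    For each genus, fits ``clr ~ factor + covariates`` with dummy coding and
    tests the factor jointly with a partial F-test; p-values are BH adjusted
    across genera. The reported coefficient is the first non-reference level
    of the factor (the planted-shift estimate in two-level designs).
    """

    def __init__(
        self,
        clr: pd.DataFrame,
        factor: Sequence,
        covariates: Mapping[str, Sequence] | None = None,
        factor_name: str = "factor",
    ):
        self.clr = clr
        self.factor = pd.Series(list(factor), index=clr.index, name=factor_name)
        self.covariates = {
            k: pd.Series(list(v), index=clr.index) for k, v in (covariates or {}).items()
        }

    def _design(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        f_dum = pd.get_dummies(self.factor, drop_first=True, dtype=float)
        f_cols = list(f_dum.columns)
        parts = [pd.Series(1.0, index=self.clr.index, name="intercept"), f_dum]
        for name, series in self.covariates.items():
            parts.append(pd.get_dummies(series, drop_first=True, prefix=name, dtype=float))
        x = pd.concat(parts, axis=1)
        xv = x.to_numpy(dtype=float)
        if np.linalg.matrix_rank(xv) < xv.shape[1]:
            raise ValueError(
                f"rank-deficient design: factor {self.factor.name!r} is collinear "
                f"with covariates {list(self.covariates)}"
            )
        f_idx = np.array([x.columns.get_loc(c) for c in f_cols])
        return xv, f_idx, f_cols

    def fit(self) -> ClrGenusModelsResult:
        import statsmodels.api as sm

        xv, f_idx, f_cols = self._design()
        rows = []
        for genus in self.clr.columns:
            y = self.clr[genus].to_numpy(dtype=float)
            model = sm.OLS(y, xv).fit()
            contrast = np.zeros((len(f_idx), xv.shape[1]))
            contrast[np.arange(len(f_idx)), f_idx] = 1.0
            ftest = model.f_test(contrast)
            rows.append(
                {
                    "genus": genus,
                    "coef": float(model.params[f_idx[0]]),
                    "se": float(model.bse[f_idx[0]]),
                    "p": float(ftest.pvalue),
                }
            )
        table = pd.DataFrame(rows)
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        return ClrGenusModelsResult(table=table)


def clr_genus_models(
    clr: pd.DataFrame,
    factor: Sequence,
    covariates: Mapping[str, Sequence] | None = None,
) -> ClrGenusModelsResult:
    """Functional wrapper around :class:`ClrGenusModels`."""
    return ClrGenusModels(clr, factor, covariates).fit()


# ---------------------------------------------------------------------------
# classical group comparisons


class GroupTest(str, Enum):
    KRUSKAL_WALLIS_DUNN = "KRUSKAL_WALLIS_DUNN"
    MANN_WHITNEY = "MANN_WHITNEY"
    SPEARMAN = "SPEARMAN"
    FISHER = "FISHER"


@dataclass
class GroupTestResult:
    test: GroupTest
    statistic: float
    p: float
    groups: list[str]
    fdr: float | None = None
    posthoc: pd.DataFrame | None = None
    note: str | None = None


def group_compare(
    values: Sequence[float],
    grouping: Sequence,
    test: GroupTest | str,
) -> GroupTestResult:
    """Compare per-sample values across groups with the requested test.

    ``SPEARMAN`` treats ``grouping`` as a second continuous vector;
    ``FISHER`` expects binary values and a two-level grouping;
    ``KRUSKAL_WALLIS_DUNN`` attaches a Dunn post-hoc frame (BH within the
    omnibus family).
    """
    test = GroupTest(test)
    values = np.asarray(values, dtype=float)
    if test is GroupTest.SPEARMAN:
        other = np.asarray(grouping, dtype=float)
        if np.unique(values).size < 2 or np.unique(other).size < 2:
            warnings.warn("degenerate ranks: Spearman rho undefined", stacklevel=2)
            return GroupTestResult(test, math.nan, math.nan, [], note="MISSING")
        rho, p = sps.spearmanr(values, other)
        return GroupTestResult(test, float(rho), float(p), [])

    series = pd.Series(values)
    labels = pd.Series(list(grouping))
    groups = {str(g): series[labels == g].to_numpy() for g in pd.unique(labels)}
    if any(len(v) == 0 for v in groups.values()) or len(groups) < 2:
        raise ValueError("each group needs at least one observation, and >= 2 groups")

    if test is GroupTest.MANN_WHITNEY:
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        (ga, gb) = groups.values()
        stat, p = sps.mannwhitneyu(ga, gb, alternative="two-sided")
        return GroupTestResult(test, float(stat), float(p), list(groups))
    if test is GroupTest.KRUSKAL_WALLIS_DUNN:
        stat, p = sps.kruskal(*groups.values())
        post = dunn_posthoc(groups) if len(groups) > 2 else None
        return GroupTestResult(test, float(stat), float(p), list(groups), posthoc=post)
    # FISHER: binary values x two groups
    if len(groups) != 2:
        raise ValueError("Fisher's exact test requires exactly two groups")
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("Fisher's exact test requires binary (0/1) values")
    (ga, gb) = groups.values()
    res = fisher_exact_2x2(
        int(ga.sum()), int(len(ga) - ga.sum()), int(gb.sum()), int(len(gb) - gb.sum())
    )
    return GroupTestResult(test, res.odds_ratio, res.p, list(groups))


def median_range_summary(values: Sequence[float]) -> str:
    """Publication-style "median (min-max)" summary with read-count rounding."""
    arr = np.asarray(values, dtype=float)
    med = round_half_away(float(np.median(arr)))
    return f"{med} ({round_half_away(arr.min())}-{round_half_away(arr.max())})"
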