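"""Mother-infant bacterial ASV-sharing analysis.

Milk samples are paired with every sample of a second body site; pairs from
the same family are "related", all cross-family pairs are "unrelated"
(the comparison group). For genera detected in both members of at least two
related pairs, a sharing event is the presence of an identical ASV sequence
in both members of a pair. Per genus, the sharing frequency in related vs
unrelated pairs is compared with a two-sided Fisher's exact test, BH-adjusted
across the genera of one comparison panel. ASV relatedness beyond exact
identity is summarised by progressive multiple sequence alignment, Hamming
distance matrices, and neighbour-joining trees.

Sharing identity is exact normalized-sequence equality and is alignment-free;
the MSA/Hamming machinery serves the non-zero distances and the trees
(aligning identical strings cannot change their equality).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .datamodel import AsvRecord, AsvTable, DistanceMatrix, SampleMeta, SampleType
from .stats import FisherResult, bh_adjust, fisher_exact_2x2  # re-exported

__all__ = [
    "Alignment",
    "PairRecord",
    "PairSet",
    "PairSharingCall",
    "SharingAnalysis",
    "SharingResults",
    "SharingStatus",
    "SharingTestResult",
    "classify_pair_sharing",
    "enumerate_pairs",
    "fisher_exact_2x2",
    "hamming_matrix",
    "nj_tree",
    "progressive_msa",
    "select_candidate_genera",
    "sharing_tests",
    "stack_alignment",
]


# ---------------------------------------------------------------------------
# pair enumeration


@dataclass(frozen=True)
class PairRecord:
    sample_a: str
    sample_b: str
    related: bool
    family_a: str
    family_b: str


@dataclass
class PairSet:
    comparison: str
    records: list[PairRecord]

    @property
    def n_related(self) -> int:
        return sum(r.related for r in self.records)

    @property
    def n_unrelated(self) -> int:
        return sum(not r.related for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def enumerate_pairs(
    meta: Sequence[SampleMeta],
    type_a: SampleType,
    type_b: SampleType,
    replicate_policy: str = "error",
) -> PairSet:
    """Enumerate all (type_a, type_b) sample pairs with the related flag.

    Every sample of ``type_a`` is paired with every sample of ``type_b``
    (self-pairs excluded); a pair is related iff both samples belong to the
    same family. A family contributing more than one sample of a type is an
    error under the default policy; ``replicate_policy="first"`` keeps the
    lowest-numbered replicate instead.
    """
    if replicate_policy not in ("error", "first"):
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")

    def pick(stype: SampleType) -> list[SampleMeta]:
        chosen: dict[str, SampleMeta] = {}
        for m in sorted(
            (m for m in meta if m.sample_type is stype and m.family_id is not None),
            key=lambda m: (m.family_id, m.replicate, m.sample_id),
        ):
            if m.family_id in chosen:
                if replicate_policy == "error":
                    raise ValueError(
                        f"family {m.family_id} has multiple {stype.value} samples; "
                        "choose a replicate policy"
                    )
                continue
            chosen[m.family_id] = m
        return list(chosen.values())

    a_samples, b_samples = pick(type_a), pick(type_b)
    if not a_samples or not b_samples:
        raise ValueError(f"no samples of both types {type_a.value}, {type_b.value}")
    records = [
        PairRecord(
            sample_a=a.sample_id,
            sample_b=b.sample_id,
            related=a.family_id == b.family_id,
            family_a=a.family_id,
            family_b=b.family_id,
        )
        for a in a_samples
        for b in b_samples
        if a.sample_id != b.sample_id
    ]
    return PairSet(comparison=f"{type_a.value}_vs_{type_b.value}", records=records)


# ---------------------------------------------------------------------------
# candidate genera and per-pair sharing calls


def _genus_asvs(taxonomy: pd.DataFrame, table: AsvTable) -> dict[str, list[str]]:
    by_genus: dict[str, list[str]] = {}
    for asv in table.asv_ids:
        by_genus.setdefault(str(taxonomy.loc[asv, "genus"]), []).append(asv)
    return by_genus


def select_candidate_genera(
    table: AsvTable,
    taxonomy: pd.DataFrame,
    pairs: PairSet,
    min_related_pairs: int = 2,
) -> list[str]:
    """Genera detected (count >= 1) in BOTH members of at least
    ``min_related_pairs`` related pairs."""
    by_genus = _genus_asvs(taxonomy, table)
    related = [r for r in pairs.records if r.related]
    out = []
    for genus, asvs in by_genus.items():
        sub = table.counts[asvs]
        present = sub.sum(axis=1) > 0
        n = sum(
            bool(present.get(r.sample_a, False)) and bool(present.get(r.sample_b, False))
            for r in related
        )
        if n >= min_related_pairs:
            out.append(genus)
    return sorted(out)


class SharingStatus(str, Enum):
    ABSENT_IN_ONE_OR_BOTH = "ABSENT_IN_ONE_OR_BOTH"
    PRESENT_NOT_SHARED = "PRESENT_NOT_SHARED"
    SHARED = "SHARED"


@dataclass(frozen=True)
class PairSharingCall:
    pair: PairRecord
    genus: str
    status: SharingStatus
    shared_asv_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status is SharingStatus.SHARED) != bool(self.shared_asv_ids):
            raise ValueError("SHARED status iff shared_asv_ids is non-empty")


def classify_pair_sharing(
    pair: PairRecord,
    genus: str,
    table: AsvTable,
    records: Mapping[str, AsvRecord] | Sequence[AsvRecord],
    taxonomy: pd.DataFrame,
    min_count: int = 1,
) -> PairSharingCall:
    """Call one pair x genus: SHARED when an identical normalized sequence of
    the genus reaches ``min_count`` reads in both samples."""
    if not isinstance(records, Mapping):
        records = {r.asv_id: r for r in records}
    asvs = [a for a in table.asv_ids if str(taxonomy.loc[a, "genus"]) == genus]
    row_a = table.counts.loc[pair.sample_a, asvs]
    row_b = table.counts.loc[pair.sample_b, asvs]
    present_a = {a for a in asvs if row_a[a] >= min_count}
    present_b = {a for a in asvs if row_b[a] >= min_count}
    if not present_a or not present_b:
        return PairSharingCall(pair, genus, SharingStatus.ABSENT_IN_ONE_OR_BOTH)
    seqs_a = {records[a].sequence for a in present_a}
    seqs_b = {records[a].sequence for a in present_b}
    shared_seqs = seqs_a & seqs_b
    if not shared_seqs:
        return PairSharingCall(pair, genus, SharingStatus.PRESENT_NOT_SHARED)
    shared_ids = tuple(
        sorted(a for a in present_a | present_b if records[a].sequence in shared_seqs)
    )
    return PairSharingCall(pair, genus, SharingStatus.SHARED, shared_ids)


# ---------------------------------------------------------------------------
# progressive multiple sequence alignment


@dataclass
class Alignment:
    """Gapped equal-length rows over {A,C,G,T,N,-}; degapping recovers inputs."""

    asv_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.asv_ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, asv_id: str) -> str:
        return self.rows[self.asv_ids.index(asv_id)].replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.asv_ids, self.rows))


def stack_alignment(records: Sequence[AsvRecord]) -> Alignment:
    """Trivial gap-free alignment of equal-length sequences (substitution-only
    pools need no gaps)."""
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError("stack_alignment requires equal-length sequences; run progressive_msa")
    return Alignment([r.asv_id for r in records], [r.sequence for r in records])


_ALPHA = "ACGTN-"
_ALPHA_IDX = {c: i for i, c in enumerate(_ALPHA)}


def _pairwise_identity_distance(seqs: list[str], match, mismatch, gap_open, gap_extend):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            counts = aln.counts()
            length = counts.gaps + counts.identities + counts.mismatches
            d[i, j] = d[j, i] = 1.0 - counts.identities / length
    return d


def _profile_columns(rows: list[str]) -> np.ndarray:
    """Column symbol-count matrix (L x 6) of a gapped profile."""
    arr = np.array([[_ALPHA_IDX[c] for c in r] for r in rows], dtype=np.int8)
    counts = np.zeros((arr.shape[1], len(_ALPHA)), dtype=float)
    for k in range(len(_ALPHA)):
        counts[:, k] = (arr == k).sum(axis=0)
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], smat: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) global alignment of two profiles.

    Column-pair score is the average-of-pairs over symbol counts; new gap
    columns cost open/extend regardless of profile size. Ties are broken by
    state priority M (substitution) > X (gap in B) > Y (gap in A).
    """
    ca, cb = _profile_columns(rows_a), _profile_columns(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    # average-of-pairs column score keeps gap penalties on the single-sequence
    # scale regardless of profile sizes
    score = (ca @ smat @ cb.T) / (len(rows_a) * len(rows_b))
    ninf = -np.inf
    m = np.full((la + 1, lb + 1), ninf)
    x = np.full((la + 1, lb + 1), ninf)  # gap in B (consume A column)
    y = np.full((la + 1, lb + 1), ninf)  # gap in A (consume B column)
    m[0, 0] = 0.0
    if la:
        x[1:, 0] = gap_open + gap_extend * np.arange(la)
    if lb:
        y[0, 1:] = gap_open + gap_extend * np.arange(lb)
    for i in range(1, la + 1):
        prev_best = np.maximum(m[i - 1], np.maximum(x[i - 1], y[i - 1]))
        m[i, 1:] = score[i - 1] + prev_best[:-1]
        x[i] = np.maximum(np.maximum(m[i - 1], y[i - 1]) + gap_open, x[i - 1] + gap_extend)
        x[i, 0] = gap_open + gap_extend * (i - 1)
        # Y within the row: affine closed form via running maximum
        t = np.maximum(m[i, :-1], x[i, :-1]) + gap_open - gap_extend * np.arange(lb)
        y[i, 1:] = gap_extend * np.arange(1, lb + 1) + np.maximum.accumulate(t) - gap_extend
        y[i, 0] = ninf
    # traceback, priority M > X > Y
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    finals = (m[la, lb], x[la, lb], y[la, lb])
    state = int(np.argmax(finals))  # argmax takes first maximum: M > X > Y
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M: consume a column from both
            i, j = i - 1, j - 1
            out_a.append("col")
            out_b.append("col")
            if i == 0 and j == 0:
                break
            cand = (m[i, j], x[i, j], y[i, j])
            state = int(np.argmax(cand))
        elif state == 1:  # X: consume A column, gap in B
            out_a.append("col")
            out_b.append("gap")
            if i > 1 and abs(x[i, j] - (x[i - 1, j] + gap_extend)) <= tol:
                state = 1
            elif m[i - 1, j] >= y[i - 1, j] - tol:
                state = 0
            else:
                state = 2
            i -= 1
        else:  # Y: gap in A, consume B column
            out_a.append("gap")
            out_b.append("col")
            if j > 1 and abs(y[i, j] - (y[i, j - 1] + gap_extend)) <= tol:
                state = 2
            elif m[i, j - 1] >= x[i, j - 1] - tol:
                state = 0
            else:
                state = 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    out_a.reverse()
    out_b.reverse()
    new_a = _emit(rows_a, out_a)
    new_b = _emit(rows_b, out_b)
    return new_a, new_b


def _emit(rows: list[str], ops: list[str]) -> list[str]:
    out = []
    for r in rows:
        buf = []
        k = 0
        for op in ops:
            if op == "col":
                buf.append(r[k])
                k += 1
            else:
                buf.append("-")
        out.append("".join(buf))
    return out


def progressive_msa(
    records: Sequence[AsvRecord],
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Alignment:
    """ClustalW-style progressive multiple sequence alignment.

    All-pairs global affine-gap alignments give identity distances
    (1 - fraction identical columns); an average-linkage guide tree fixes
    the merge order; profiles are then aligned progressively with
    sum-of-pairs column scoring. Deterministic for fixed parameters and
    input order (ties by label order and by state priority).
    """
    if len(records) < 2:
        raise ValueError("MSA needs at least two sequences")
    for r in records:
        if not r.sequence:
            raise ValueError(f"{r.asv_id}: empty sequence")
    ids = [r.asv_id for r in records]
    seqs = [r.sequence for r in records]

    # substitution matrix over the gapped alphabet; existing gaps score 0
    smat = np.zeros((len(_ALPHA), len(_ALPHA)))
    for a in "ACGTN":
        for b in "ACGTN":
            smat[_ALPHA_IDX[a], _ALPHA_IDX[b]] = match if a == b else mismatch
    smat[_ALPHA_IDX["N"], :] = 0.0
    smat[:, _ALPHA_IDX["N"]] = 0.0
    smat[_ALPHA_IDX["-"], :] = 0.0
    smat[:, _ALPHA_IDX["-"]] = 0.0

    d = _pairwise_identity_distance(seqs, match, mismatch, gap_open, gap_extend)
    if len(records) == 2:
        merged = _align_profiles([seqs[0]], [seqs[1]], smat, gap_open, gap_extend)
        rows = {ids[0]: merged[0][0], ids[1]: merged[1][0]}
        return Alignment(ids, [rows[i] for i in ids])

    z = sch.linkage(squareform(d, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        k: ([ids[k]], [seqs[k]]) for k in range(len(ids))
    }
    nxt = len(ids)
    for row in z:
        a, b = int(row[0]), int(row[1])
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b, smat, gap_open, gap_extend)
        profiles[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows) = profiles.popitem()[1]
    order = {i: k for k, i in enumerate(final_ids)}
    aln = Alignment(ids, [final_rows[order[i]] for i in ids])
    for r in records:  # degapping must recover every input
        assert aln.degapped(r.asv_id) == r.sequence
    return aln


# ---------------------------------------------------------------------------
# Hamming distances and NJ trees


def hamming_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise count of differing alignment columns.

    A gap against a base counts as a difference; gap against gap counts as
    equal, so distance 0 holds iff the gapped rows are identical.
    """
    arr = np.array([list(r) for r in alignment.rows])
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (arr[i + 1 :] != arr[i]).sum(axis=1)
    d = d + d.T
    return DistanceMatrix(alignment.asv_ids, d)


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbour-joining tree from a distance matrix, serialized as Newick.

    Uses the standard Q-criterion agglomeration; negative branch lengths are
    clamped to zero (with a warning). Deterministic for a given label order.
    """
    if d.n < 2:
        raise ValueError("NJ needs at least two taxa")
    if d.n == 2:
        a, b = d.labels
        return f"({a}:{d.values[0, 1] / 2.0},{b}:{d.values[0, 1] / 2.0});"
    from skbio.tree import nj as skbio_nj

    tree = skbio_nj(d.to_skbio(), neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0", stacklevel=2)
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# per-genus exact tests


@dataclass(frozen=True)
class SharingTestResult:
    genus: str
    comparison: str
    related_shared: int
    related_total: int
    unrelated_shared: int
    unrelated_total: int
    odds_ratio: float
    p: float
    fdr: float = math.nan

    @property
    def stars(self) -> str:
        if self.fdr < 0.001:
            return "***"
        if self.fdr < 0.01:
            return "**"
        if self.fdr < 0.05:
            return "*"
        return ""

    @property
    def related_fraction(self) -> float:
        return self.related_shared / self.related_total if self.related_total else math.nan


def sharing_tests(
    calls: Sequence[PairSharingCall],
    comparison: str,
    denominator: str = "all",
) -> list[SharingTestResult]:
    """Per-genus 2x2 Fisher tests of sharing in related vs unrelated pairs.

    ``denominator="all"`` counts every pair in the not-shared margin
    (ABSENT pooled with PRESENT_NOT_SHARED); ``"present-both"`` restricts
    the table to pairs where the genus is present in both members. BH
    adjustment runs across the genera of this comparison (one panel, one
    family).
    """
    if denominator not in ("all", "present-both"):
        raise ValueError(f"unknown denominator {denominator!r}")
    by_genus: dict[str, list[PairSharingCall]] = {}
    for c in calls:
        by_genus.setdefault(c.genus, []).append(c)
    results = []
    for genus in sorted(by_genus):
        rel_s = rel_t = unr_s = unr_t = 0
        for c in by_genus[genus]:
            if denominator == "present-both" and c.status is SharingStatus.ABSENT_IN_ONE_OR_BOTH:
                continue
            shared = c.status is SharingStatus.SHARED
            if c.pair.related:
                rel_t += 1
                rel_s += shared
            else:
                unr_t += 1
                unr_s += shared
        if rel_t + unr_t == 0:
            warnings.warn(f"{genus}: no pairs under denominator={denominator!r}; skipped", stacklevel=2)
            continue
        res = fisher_exact_2x2(rel_s, rel_t - rel_s, unr_s, unr_t - unr_s)
        results.append(
            SharingTestResult(
                genus=genus,
                comparison=comparison,
                related_shared=rel_s,
                related_total=rel_t,
                unrelated_shared=unr_s,
                unrelated_total=unr_t,
                odds_ratio=res.odds_ratio,
                p=res.p,
            )
        )
    fdrs = bh_adjust([r.p for r in results])
    return [
        SharingTestResult(**{**r.__dict__, "fdr": float(q)})
        for r, q in zip(results, fdrs)
    ]


# ---------------------------------------------------------------------------
# model-style front end


@dataclass
class SharingResults:
    """Fitted sharing analysis for one body-site comparison."""

    pairs: PairSet
    candidate_genera: list[str]
    calls: list[PairSharingCall]
    tests: list[SharingTestResult]
    denominator: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            rows.append(
                {
                    "genus": t.genus,
                    "comparison": t.comparison,
                    "related_shared": t.related_shared,
                    "related_total": t.related_total,
                    "unrelated_shared": t.unrelated_shared,
                    "unrelated_total": t.unrelated_total,
                    "related_pct": 100.0 * t.related_shared / t.related_total
                    if t.related_total
                    else math.nan,
                    "unrelated_pct": 100.0 * t.unrelated_shared / t.unrelated_total
                    if t.unrelated_total
                    else math.nan,
                    "odds_ratio": t.odds_ratio,
                    "p": t.p,
                    "fdr": t.fdr,
                    "stars": t.stars,
                }
            )
        return pd.DataFrame(rows)

    def status_percentages(self) -> pd.DataFrame:
        """Percentage of related/unrelated pairs per sharing status and genus
        (the stacked-bar representation of a sharing panel)."""
        rows = []
        for genus in self.candidate_genera:
            for related in (True, False):
                sub = [
                    c for c in self.calls if c.genus == genus and c.pair.related == related
                ]
                n = len(sub)
                for status in SharingStatus:
                    k = sum(c.status is status for c in sub)
                    rows.append(
                        {
                            "genus": genus,
                            "group": "related" if related else "unrelated",
                            "status": status.value,
                            "pct": 100.0 * k / n if n else math.nan,
                        }
                    )
        return pd.DataFrame(rows)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_a": c.pair.sample_a,
                    "sample_b": c.pair.sample_b,
                    "related": c.pair.related,
                    "genus": c.genus,
                    "status": c.status.value,
                    "shared_asv_ids": ";".join(c.shared_asv_ids),
                }
                for c in self.calls
            ]
        )


class SharingAnalysis:
    """Sharing analysis of one body-site comparison, statsmodels-style.

    Build from the dataset objects, then :meth:`fit` enumerates pairs,
    selects candidate genera, calls per-pair sharing and runs the per-genus
    exact tests.
    """

    def __init__(
        self,
        table: AsvTable,
        meta: Sequence[SampleMeta],
        records: Sequence[AsvRecord],
        taxonomy: pd.DataFrame,
        type_a: SampleType = SampleType.MILK,
        type_b: SampleType = SampleType.INFANT_ORAL,
        min_related_pairs: int = 2,
        denominator: str = "all",
        min_count: int = 1,
        replicate_policy: str = "error",
    ):
        self.table = table
        self.meta = list(meta)
        self.records = {r.asv_id: r for r in records}
        self.taxonomy = taxonomy
        self.type_a = type_a
        self.type_b = type_b
        self.min_related_pairs = min_related_pairs
        self.denominator = denominator
        self.min_count = min_count
        self.replicate_policy = replicate_policy

    def fit(self) -> SharingResults:
        pairs = enumerate_pairs(
            self.meta, self.type_a, self.type_b, self.replicate_policy
        )
        genera = select_candidate_genera(
            self.table, self.taxonomy, pairs, self.min_related_pairs
        )
        calls = [
            classify_pair_sharing(
                rec, genus, self.table, self.records, self.taxonomy, self.min_count
            )
            for genus in genera
            for rec in pairs.records
        ]
        tests = sharing_tests(calls, pairs.comparison, self.denominator)
        return SharingResults(
            pairs=pairs,
            candidate_genera=genera,
            calls=calls,
            tests=tests,
            denominator=self.denominator,
        )

    def genus_alignment(self, genus: str) -> Alignment:
        """Alignment of the genus's observed ASVs (gap-free stack when all
        sequences share one length, progressive MSA otherwise)."""
        recs = [
            self.records[a]
            for a in self.table.asv_ids
            if str(self.taxonomy.loc[a, "genus"]) == genus
            and self.table.counts[a].sum() > 0
        ]
        if len(recs) < 2:
            raise ValueError(f"{genus}: need >= 2 observed ASVs for an alignment")
        if len({len(r.sequence) for r in recs}) == 1:
            return stack_alignment(recs)
        return progressive_msa(recs)

    def genus_tree(self, genus: str) -> str:
        """Neighbour-joining Newick tree over the genus's ASV Hamming matrix."""
        return nj_tree(hamming_matrix(self.genus_alignment(genus)))
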