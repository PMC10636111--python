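"""Pair enumeration, sharing calls, MSA, Hamming, exact tests and NJ trees."""

import itertools
import math
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from milkshare.datamodel import (
    AsvRecord,
    AsvTable,
    DistanceMatrix,
    SampleMeta,
    SampleType,
)
from milkshare.stats import bh_adjust
from milkshare.sharing import (
    Alignment,
    PairRecord,
    PairSharingCall,
    SharingAnalysis,
    SharingStatus,
    classify_pair_sharing,
    enumerate_pairs,
    fisher_exact_2x2,
    hamming_matrix,
    nj_tree,
    progressive_msa,
    select_candidate_genera,
    sharing_tests,
    stack_alignment,
)
from milkshare.synthetic import GenusSpec, SimConfig, generate_genus_pool, simulate_cohort


# ---------------------------------------------------------------------------
# pair enumeration


def _family_meta(n_families, type_b=SampleType.MATERNAL_FAECES, drop_last_b=False):
    meta = []
    for f in range(1, n_families + 1):
        meta.append(SampleMeta(f"F{f:02d}_MILK", SampleType.MILK, family_id=f"F{f:02d}"))
        if drop_last_b and f == n_families:
            continue
        meta.append(SampleMeta(f"F{f:02d}_B", type_b, family_id=f"F{f:02d}"))
    return meta


def test_pair_counts_complete_cohort():
    """14 complete families give 14 related and 14*13 = 182 unrelated pairs."""
    pairs = enumerate_pairs(
        _family_meta(14), SampleType.MILK, SampleType.MATERNAL_FAECES
    )
    assert pairs.n_related == 14
    assert pairs.n_unrelated == 182


def test_pair_counts_one_family_incomplete():
    """14 milk vs 13 maternal faecal samples give 13 related, 169 unrelated."""
    pairs = enumerate_pairs(
        _family_meta(14, drop_last_b=True), SampleType.MILK, SampleType.MATERNAL_FAECES
    )
    assert pairs.n_related == 13
    assert pairs.n_unrelated == 169


def test_pair_counts_two_families_exhaustive():
    pairs = enumerate_pairs(_family_meta(2), SampleType.MILK, SampleType.MATERNAL_FAECES)
    got = {(r.sample_a, r.sample_b, r.related) for r in pairs.records}
    assert got == {
        ("F01_MILK", "F01_B", True),
        ("F01_MILK", "F02_B", False),
        ("F02_MILK", "F01_B", False),
        ("F02_MILK", "F02_B", True),
    }


def test_pair_totals_match_double_loop():
    """related = #complete families; related + unrelated = |A| x |B|."""
    meta = _family_meta(9, drop_last_b=True)
    pairs = enumerate_pairs(meta, SampleType.MILK, SampleType.MATERNAL_FAECES)
    n_a = sum(m.sample_type is SampleType.MILK for m in meta)
    n_b = sum(m.sample_type is SampleType.MATERNAL_FAECES for m in meta)
    assert pairs.n_related + pairs.n_unrelated == n_a * n_b
    assert pairs.n_related == 8
    assert len({(r.sample_a, r.sample_b) for r in pairs.records}) == len(pairs.records)


def test_pair_replicate_policy():
    meta = _family_meta(3)
    meta.append(
        SampleMeta("F01_MILK_rep2", SampleType.MILK, family_id="F01", replicate=2)
    )
    with pytest.raises(ValueError, match="F01"):
        enumerate_pairs(meta, SampleType.MILK, SampleType.MATERNAL_FAECES)
    pairs = enumerate_pairs(
        meta, SampleType.MILK, SampleType.MATERNAL_FAECES, replicate_policy="first"
    )
    used = {r.sample_a for r in pairs.records}
    assert "F01_MILK" in used and "F01_MILK_rep2" not in used


# ---------------------------------------------------------------------------
# candidate genera and per-pair calls


def _sharing_fixture():
    # F1: same Strep ASV in both; F2: different Strep ASVs; F3: absent in B
    counts = pd.DataFrame(
        {
            "strep1": [5, 3, 0, 0, 2, 0],
            "strep2": [0, 0, 4, 0, 0, 0],
            "strep3": [0, 0, 0, 6, 0, 0],
            "staph1": [1, 1, 1, 1, 1, 1],
        },
        index=["F01_MILK", "F01_B", "F02_MILK", "F02_B", "F03_MILK", "F03_B"],
    )
    table = AsvTable(counts)
    meta = []
    for f in (1, 2, 3):
        meta.append(SampleMeta(f"F{f:02d}_MILK", SampleType.MILK, family_id=f"F{f:02d}"))
        meta.append(SampleMeta(f"F{f:02d}_B", SampleType.INFANT_ORAL, family_id=f"F{f:02d}"))
    records = [
        AsvRecord("strep1", "ACGTACGT", genus="Streptococcus"),
        AsvRecord("strep2", "ACGAACGT", genus="Streptococcus"),
        AsvRecord("strep3", "ACGAACGA", genus="Streptococcus"),
        AsvRecord("staph1", "TTGTACGT", genus="Staphylococcus"),
    ]
    taxonomy = pd.DataFrame(
        {
            "genus": ["Streptococcus", "Streptococcus", "Streptococcus", "Staphylococcus"],
            "species": ["UNCLASSIFIED"] * 4,
        },
        index=pd.Index(["strep1", "strep2", "strep3", "staph1"], name="asv_id"),
    )
    return table, meta, records, taxonomy


def test_select_candidate_genera_thresholds():
    table, meta, records, tax = _sharing_fixture()
    pairs = enumerate_pairs(meta, SampleType.MILK, SampleType.INFANT_ORAL)
    # Staph present in both members of all 3 related pairs; Strep in 2 of 3
    assert select_candidate_genera(table, tax, pairs) == ["Staphylococcus", "Streptococcus"]
    assert select_candidate_genera(table, tax, pairs, min_related_pairs=3) == [
        "Staphylococcus"
    ]
    # drop strep from F2_B: genus in both members of only 1 related pair
    c2 = table.counts.copy()
    c2.loc["F02_B", "strep3"] = 0
    assert select_candidate_genera(AsvTable(c2), tax, pairs) == ["Staphylococcus"]


def test_classify_pair_sharing_statuses():
    table, meta, records, tax = _sharing_fixture()
    pairs = enumerate_pairs(meta, SampleType.MILK, SampleType.INFANT_ORAL)
    rec_by = {(r.sample_a, r.sample_b): r for r in pairs.records}
    shared = classify_pair_sharing(
        rec_by[("F01_MILK", "F01_B")], "Streptococcus", table, records, tax
    )
    assert shared.status is SharingStatus.SHARED
    assert shared.shared_asv_ids == ("strep1",)
    near = classify_pair_sharing(
        rec_by[("F02_MILK", "F02_B")], "Streptococcus", table, records, tax
    )
    assert near.status is SharingStatus.PRESENT_NOT_SHARED  # Hamming 1 apart
    absent = classify_pair_sharing(
        rec_by[("F03_MILK", "F03_B")], "Streptococcus", table, records, tax
    )
    assert absent.status is SharingStatus.ABSENT_IN_ONE_OR_BOTH


def test_sharing_symmetric_in_pair_order():
    table, meta, records, tax = _sharing_fixture()
    a = PairRecord("F01_MILK", "F01_B", True, "F01", "F01")
    b = PairRecord("F01_B", "F01_MILK", True, "F01", "F01")
    ca = classify_pair_sharing(a, "Streptococcus", table, records, tax)
    cb = classify_pair_sharing(b, "Streptococcus", table, records, tax)
    assert ca.status is cb.status and ca.shared_asv_ids == cb.shared_asv_ids


# ---------------------------------------------------------------------------
# progressive MSA


def _alignment_score(row_a, row_b, match=2.0, mismatch=-1.0, open_=-5.0, ext=-2.0):
    """Score a pairwise alignment from its gapped rows (affine runs)."""
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
    for row in (row_a, row_b):
        k = 0
        while k < len(row):
            if row[k] == "-":
                run = 0
                while k < len(row) and row[k] == "-":
                    run += 1
                    k += 1
                score += open_ + ext * (run - 1)
            else:
                k += 1
    return score


def test_msa_identical_sequences_gap_free():
    records = [AsvRecord(f"a{i}", "ACGTACGTAC") for i in range(4)]
    aln = progressive_msa(records)
    assert aln.length == 10
    assert all(r == "ACGTACGTAC" for r in aln.rows)


def test_msa_single_mismatch_pair():
    aln = progressive_msa([AsvRecord("a", "ACGTACGT"), AsvRecord("b", "ACGAACGT")])
    assert aln.rows == ["ACGTACGT", "ACGAACGT"]  # gap-free, one mismatch column


def test_msa_single_insertion_pair():
    aln = progressive_msa([AsvRecord("a", "ACGTACGT"), AsvRecord("b", "ACGTTACGT")])
    assert aln.length == 9
    assert aln.rows[1] == "ACGTTACGT"
    assert aln.rows[0].count("-") == 1
    assert aln.degapped("a") == "ACGTACGT"


def test_msa_pairwise_scores_are_optimal():
    """Profile alignment of two single sequences reaches the optimal global
    affine-gap score reported by an independent pairwise aligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    rng = np.random.default_rng(17)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(8, 25)))
        b = list(a)
        # random edits: substitutions and indels
        for _ in range(rng.integers(1, 4)):
            op = rng.integers(0, 3)
            pos = int(rng.integers(0, len(b)))
            if op == 0:
                b[pos] = "ACGT"[rng.integers(0, 4)]
            elif op == 1 and len(b) > 2:
                del b[pos]
            else:
                b.insert(pos, "ACGT"[rng.integers(0, 4)])
        b = "".join(b)
        aln = progressive_msa([AsvRecord("x", a), AsvRecord("y", b)])
        ours = _alignment_score(aln.rows[0], aln.rows[1])
        assert ours == pytest.approx(aligner.score(a, b), abs=1e-9)


def test_msa_multiple_sequences_consistent():
    records = [
        AsvRecord("a", "ACGTACGTAAGG"),
        AsvRecord("b", "ACGAACGTAAGG"),
        AsvRecord("c", "ACGTACGTAAG"),
        AsvRecord("d", "ACCTACGTTAAGG"),
    ]
    aln = progressive_msa(records)
    assert len({len(r) for r in aln.rows}) == 1
    for r in records:
        assert aln.degapped(r.asv_id) == r.sequence
    # determinism
    aln2 = progressive_msa(records)
    assert aln.rows == aln2.rows


def test_msa_substitution_only_pool_stays_gap_free():
    pool = generate_genus_pool("G", 8, 402, 0.03, seed=2)
    aln = progressive_msa(pool.records)
    assert aln.length == 402
    assert all("-" not in r for r in aln.rows)


def test_msa_rejects_degenerate_input():
    with pytest.raises(ValueError):
        progressive_msa([AsvRecord("a", "ACGT")])


# ---------------------------------------------------------------------------
# Hamming matrices


def test_hamming_simple_cases():
    aln = Alignment(["a", "b", "c"], ["ACGT", "ACGA", "ACGT"])
    d = hamming_matrix(aln)
    assert d[("a", "b")] == 1
    assert d[("a", "c")] == 0


def test_hamming_gap_conventions():
    aln = Alignment(["a", "b", "c"], ["AC-T", "ACGT", "AC-T"])
    d = hamming_matrix(aln)
    assert d[("a", "b")] == 1  # gap vs base differs
    assert d[("a", "c")] == 0  # gap vs gap equal


def test_hamming_matches_generator_truth_and_brute_force():
    from milkshare.synthetic import brute_force_hamming

    pool = generate_genus_pool("G", 50, 420, 0.02, seed=13)
    aln = stack_alignment(pool.records)
    d = hamming_matrix(aln)
    np.testing.assert_array_equal(d.values, pool.distances.values)
    np.testing.assert_array_equal(
        d.values, brute_force_hamming([r.sequence for r in pool.records])
    )


# ---------------------------------------------------------------------------
# Fisher's exact test


def _fisher_oracle(a, b, c, d):
    """Exact two-sided p by integer enumeration over the support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = w[a]
    thresh = w_obs * (10**9 + 100) // 10**9  # (1 + 1e-7) in integer arithmetic
    return sum(v for v in w.values() if v <= thresh) / sum(w.values())


def test_fisher_symmetric_table_is_one():
    assert fisher_exact_2x2(1, 1, 1, 1).p == 1.0


def test_fisher_perfect_separation_closed_form():
    res = fisher_exact_2x2(5, 0, 0, 5)
    assert res.p == pytest.approx(2.0 / 252.0, rel=1e-12)
    assert math.isinf(res.odds_ratio)


def test_fisher_all_zero_table():
    res = fisher_exact_2x2(0, 0, 0, 0)
    assert res.p == 1.0
    assert math.isnan(res.odds_ratio)


def test_fisher_matches_enumeration_small_tables():
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    ours = fisher_exact_2x2(a, b, c, d).p
                    assert ours == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-12)


def test_fisher_matches_scipy_on_random_tables():
    from scipy.stats import fisher_exact as scipy_fisher

    rng = np.random.default_rng(23)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 25, size=4)
        ours = fisher_exact_2x2(a, b, c, d).p
        theirs = scipy_fisher([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(deadline=None, max_examples=200)
def test_bh_adjust_properties(pvals):
    """BH step-up never falls below the raw p and is monotone in p-order."""
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# sharing tests on constructed and simulated data


def _make_calls(genus, related_flags, statuses):
    calls = []
    for k, (rel, status) in enumerate(zip(related_flags, statuses)):
        pair = PairRecord(f"a{k}", f"b{k}", rel, f"FA{k}", f"FA{k}" if rel else f"FB{k}")
        shared = (f"{genus}_asv",) if status is SharingStatus.SHARED else ()
        calls.append(PairSharingCall(pair, genus, status, shared))
    return calls


def test_sharing_tests_equal_fractions_not_significant():
    """7/14 related vs 91/182 unrelated sharing: no association (p >= 0.5)."""
    rel = [True] * 14 + [False] * 182
    statuses = (
        [SharingStatus.SHARED] * 7
        + [SharingStatus.PRESENT_NOT_SHARED] * 7
        + [SharingStatus.SHARED] * 91
        + [SharingStatus.ABSENT_IN_ONE_OR_BOTH] * 91
    )
    (res,) = sharing_tests(_make_calls("G", rel, statuses), "MILK_vs_X")
    assert (res.related_shared, res.related_total) == (7, 14)
    assert (res.unrelated_shared, res.unrelated_total) == (91, 182)
    assert res.p >= 0.5


def test_sharing_tests_zero_sharing_is_null():
    rel = [True] * 14 + [False] * 30
    statuses = [SharingStatus.PRESENT_NOT_SHARED] * 44
    (res,) = sharing_tests(_make_calls("G", rel, statuses), "MILK_vs_X")
    assert res.p == 1.0


def test_sharing_tests_denominator_modes():
    rel = [True] * 4 + [False] * 4
    statuses = [
        SharingStatus.SHARED,
        SharingStatus.SHARED,
        SharingStatus.PRESENT_NOT_SHARED,
        SharingStatus.ABSENT_IN_ONE_OR_BOTH,
        SharingStatus.ABSENT_IN_ONE_OR_BOTH,
        SharingStatus.ABSENT_IN_ONE_OR_BOTH,
        SharingStatus.PRESENT_NOT_SHARED,
        SharingStatus.SHARED,
    ]
    calls = _make_calls("G", rel, statuses)
    (all_mode,) = sharing_tests(calls, "c", denominator="all")
    assert (all_mode.related_total, all_mode.unrelated_total) == (4, 4)
    (pb_mode,) = sharing_tests(calls, "c", denominator="present-both")
    assert (pb_mode.related_total, pb_mode.unrelated_total) == (3, 2)


def test_forced_cohort_recovers_planted_genus():
    """p_share=1, p_bg=0: the planted genus shares in every related pair,
    never in unrelated pairs, and reaches FDR < 0.05."""
    cfg = SimConfig(
        seed=19,
        n_families=14,
        sample_types=(SampleType.MILK, SampleType.INFANT_ORAL),
        genera=(GenusSpec("Strep", p_share=1.0, p_bg=0.0),),
        contaminants=(),
        libprep_contaminant_genera=(),
    )
    cohort = simulate_cohort(cfg)
    res = SharingAnalysis(
        cohort.table,
        cohort.meta,
        cohort.records,
        cohort.taxonomy,
        type_b=SampleType.INFANT_ORAL,
    ).fit()
    assert res.pairs.n_related == 14 and res.pairs.n_unrelated == 182
    strep = next(t for t in res.tests if t.genus == "Strep")
    assert strep.related_shared == strep.related_total == 14
    assert strep.unrelated_shared == 0
    assert strep.fdr < 0.05
    pct = res.status_percentages()
    shared_rel = pct.query("genus == 'Strep' and group == 'related' and status == 'SHARED'")
    assert shared_rel["pct"].iloc[0] == 100.0


# ---------------------------------------------------------------------------
# neighbour-joining trees


def _tip_distances(newick: str):
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_nj_two_taxa_edge_sum():
    d = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
    t = _tip_distances(nj_tree(d))
    assert t[("a", "b")] == pytest.approx(3.0)


def test_nj_four_taxon_additive_recovery():
    """AB=2, CD=2, cross distances 4: the split AB|CD with unit leaf edges
    and an internal edge of 2 reproduces every input distance."""
    labels = ["A", "B", "C", "D"]
    vals = np.array(
        [
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ],
        dtype=float,
    )
    t = _tip_distances(nj_tree(DistanceMatrix(labels, vals)))
    for (i, a) in enumerate(labels):
        for (j, b) in enumerate(labels):
            if i < j:
                assert t[(a, b)] == pytest.approx(vals[i, j], abs=1e-9)


def _random_additive_matrix(n, seed):
    """Path metric of a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    import networkx as nx

    g = nx.Graph()
    nodes = [f"t{i}" for i in range(n)]
    avail = list(nodes)
    internal = 0
    while len(avail) > 2:
        a = avail.pop(rng.integers(len(avail)))
        b = avail.pop(rng.integers(len(avail)))
        new = f"i{internal}"
        internal += 1
        g.add_edge(a, new, weight=float(rng.uniform(0.5, 3.0)))
        g.add_edge(b, new, weight=float(rng.uniform(0.5, 3.0)))
        avail.append(new)
    g.add_edge(avail[0], avail[1], weight=float(rng.uniform(0.5, 3.0)))
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i in range(n):
        for j in range(n):
            d[i, j] = paths[nodes[i]][nodes[j]]
    return nodes, d


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_reconstructs_random_additive_metrics(n):
    labels, vals = _random_additive_matrix(n, seed=100 + n)
    t = _tip_distances(nj_tree(DistanceMatrix(labels, vals)))
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((labels[i], labels[j])))
            assert t[key] == pytest.approx(vals[i, j], abs=1e-8)


def test_genus_tree_from_cohort():
    cfg = SimConfig(
        seed=29,
        n_families=6,
        sample_types=(SampleType.MILK, SampleType.INFANT_ORAL),
        genera=(GenusSpec("Strep", p_share=0.5, p_bg=0.1),),
        contaminants=(),
        libprep_contaminant_genera=(),
    )
    cohort = simulate_cohort(cfg)
    model = SharingAnalysis(
        cohort.table, cohort.meta, cohort.records, cohort.taxonomy,
        type_b=SampleType.INFANT_ORAL,
    )
    newick = model.genus_tree("Strep")
    assert newick.endswith(";")
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    n_strep = sum(
        cohort.taxonomy.loc[a, "genus"] == "Strep" and cohort.table.counts[a].sum() > 0
        for a in cohort.table.asv_ids
    )
    assert len(list(tree.tips())) == n_strep
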