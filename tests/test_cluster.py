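"""Overlap alignment vs a brute-force oracle, pair similarity symmetries,
the prefiltered similarity graph, Louvain and stable cores."""

import networkx as nx
import numpy as np
import pytest

from polycor.cluster import (
    AlignScoreParams,
    build_similarity_graph,
    louvain,
    overlap_align_score,
    pair_similarity,
    stable_cores,
)
from polycor.kmers import RepetitivePattern, count_kmers, revcomp
from polycor.seqio import ReadPair, ReadRecord
from polycor.simulate import simulate_genome, simulate_reads

from .oracles import all_strings, overlap_score_brute

P = AlignScoreParams(match=1, mismatch=-1, gap=-3, tau=5)


def test_overlap_score_stated_examples():
    assert overlap_align_score("ACGTAC", "ACGTAC", P) == 6  # perfect self-overlap
    assert overlap_align_score("TTTACG", "ACGGGG", P) == 3  # ACG suffix/prefix
    assert overlap_align_score("AAAA", "TTTT", P) == 0      # empty overlap wins


def test_overlap_score_equals_bruteforce_on_all_short_strings():
    strings = list(all_strings("AC", 4))
    for a in strings:
        for b in strings:
            assert overlap_align_score(a, b, P) == overlap_score_brute(a, b), (a, b)


def test_overlap_score_equals_bruteforce_on_seeded_longer_strings(rng):
    for _ in range(150):
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        assert overlap_align_score(a, b, P) == overlap_score_brute(a, b), (a, b)


def _pair(ordinal, s1, s2):
    return ReadPair(
        ordinal, ReadRecord("x/1", s1, "I" * len(s1), 1), ReadRecord("x/2", s2, "I" * len(s2), 2)
    )


def _rc_pair(p):
    return ReadPair(
        p.ordinal,
        ReadRecord("x/1", revcomp(p.r2.seq), "I" * len(p.r2.seq), 1),
        ReadRecord("x/2", revcomp(p.r1.seq), "I" * len(p.r1.seq), 2),
    )


def test_pair_similarity_of_identical_pairs_is_twice_read_length(rng):
    s1 = "".join(rng.choice(list("ACGT"), 60))
    s2 = "".join(rng.choice(list("ACGT"), 60))
    a = _pair(0, s1, s2)
    assert pair_similarity(a, a, P) == 120


def test_pair_similarity_symmetric_and_rc_invariant(rng):
    for _ in range(10):
        a = _pair(0, *["".join(rng.choice(list("ACGT"), 40)) for _ in range(2)])
        b = _pair(1, *["".join(rng.choice(list("ACGT"), 40)) for _ in range(2)])
        sab = pair_similarity(a, b, P)
        assert sab == pair_similarity(b, a, P)
        assert sab == pair_similarity(_rc_pair(a), _rc_pair(b), P)


def test_same_locus_pairs_score_above_tau_and_cross_locus_below(rng):
    genome = simulate_genome(length=6000, n_loci=3, seed=11)
    rs = simulate_reads(genome, coverage=20, error_rate=0.001, seed=11)
    tau_params = AlignScoreParams(match=1, mismatch=-1, gap=-3, tau=40)
    by_locus = {}
    for i in range(len(rs.pairs)):
        loc = rs.locus_of(i)
        if loc is not None:
            by_locus.setdefault(loc, []).append(rs.pairs[i])
    same = cross = 0
    same_hi = cross_lo = 0
    loci = sorted(by_locus)
    for loc in loci:
        ps = by_locus[loc][:6]
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                same += 1
                same_hi += pair_similarity(ps[i], ps[j], tau_params) >= tau_params.tau
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            for a in by_locus[loci[i]][:4]:
                for b in by_locus[loci[j]][:4]:
                    cross += 1
                    cross_lo += pair_similarity(a, b, tau_params) < tau_params.tau
    assert same_hi / same >= 0.6   # anchors overlap; mates need not
    assert cross_lo / cross >= 0.95


def test_similarity_graph_prefilter_excludes_pure_repeat_sharing():
    pat = RepetitivePattern()
    flank_a = "CAGTCGATCGTACGTAGCATCGATTCGAGCTAGCTAACGTTAGC"
    flank_b = "TGCACCTGAGTTGACCAGTTCCAAGGTCTTAGGTTCTGACCAAG"
    run = "A" * 20
    p0 = _pair(0, flank_a + run, flank_a[::-1])
    p1 = _pair(1, flank_b + run, flank_b[::-1])
    p2 = _pair(2, flank_a + run, flank_a[::-1])
    counts = count_kmers([r for p in (p0, p1, p2) for r in (p.r1, p.r2)], 15)
    g = build_similarity_graph([p0, p1, p2], counts, 5.0, AlignScoreParams(tau=30), pattern=pat)
    assert not g.has_edge(0, 1)  # share only the poly(A) run
    assert g.has_edge(0, 2)      # identical flanks
    # identical pairs: both mates overlap themselves fully
    assert g[0][2]["weight"] == pytest.approx(len(flank_a + run) + len(flank_a))


def test_similarity_graph_rejects_nonpositive_ck():
    with pytest.raises(ValueError):
        build_similarity_graph([], count_kmers([], 15), 0.0, P)


def _two_cliques(bridge=True):
    g = nx.Graph()
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(base + i, base + j, weight=1.0)
    if bridge:
        g.add_edge(0, 5, weight=1.0)
    return g


def test_louvain_leaves_edgeless_graph_as_singletons():
    g = nx.Graph()
    g.add_nodes_from(range(6))
    part = louvain(g, seed=0)
    assert sorted(map(sorted, part.communities())) == [[i] for i in range(6)]
    assert part.modularity == 0.0


def test_louvain_recovers_bridged_cliques_and_is_deterministic():
    g = _two_cliques()
    part = louvain(g, seed=7)
    assert sorted(map(sorted, part.communities())) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
    assert part.assignment == louvain(g, seed=7).assignment
    singleton_q = 0.0 - sum(
        (d / (2 * g.size(weight="weight"))) ** 2 * 0 for _, d in g.degree(weight="weight")
    )
    assert part.modularity >= singleton_q


def test_stable_cores_single_run_equals_partition():
    g = _two_cliques()
    sc = stable_cores(g, n_runs=1, theta=0.8, seed=0)
    assert sorted(map(sorted, sc.cores)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
    assert sc.unassigned == set()


def test_stable_cores_robust_across_runs_for_clique_structure():
    g = _two_cliques()
    for theta in (0.5, 0.8, 1.0):
        sc = stable_cores(g, n_runs=20, theta=theta, seed=3)
        assert sorted(map(sorted, sc.cores)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
        assert sc.unassigned == set()


def test_stable_cores_isolated_nodes_form_singleton_cores():
    g = _two_cliques()
    g.add_node(99)
    sc = stable_cores(g, n_runs=10, theta=0.9, seed=0)
    assert {99} in sc.cores
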