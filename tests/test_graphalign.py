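"""Seed finding and seed-and-extend read-to-graph correction."""

import numpy as np
import pytest

from polycor.dbg import CleanParams, build_graph, clean_graph
from polycor.graphalign import (
    GraphAlignParams,
    correct_cluster,
    extend_alignment,
    find_seeds,
)
from polycor.kmers import revcomp
from polycor.seqio import ReadRecord
from .conftest import random_seq


def _read(seq, qual=None):
    return ReadRecord("r", seq, qual or "I" * len(seq), 1)


def _mutate(seq, pos):
    alt = "A" if seq[pos] != "A" else "C"
    return seq[:pos] + alt + seq[pos + 1 :]


@pytest.fixture()
def locus(rng):
    genome = random_seq(rng, 300)
    reads = [genome[i : i + 100] for i in range(0, 201, 10)]
    return genome, build_graph(reads, 15)


def test_alien_read_yields_no_seeds(rng, locus):
    _, g = locus
    assert find_seeds(_read(random_seq(rng, 60)), g) == []


def test_error_free_read_seeds_every_window_collinearly(locus):
    genome, g = locus
    read = _read(genome[40:140])
    seeds = find_seeds(read, g)
    assert len(seeds) == 100 - 15 + 1
    assert [s.read_offset for s in seeds] == list(range(86))
    assert len({(s.node, s.strand) for s in seeds}) == 1


def test_palindromic_kmers_are_excluded_as_ambiguous():
    # at even k a self-reverse-complement k-mer sits on both strands at
    # once and cannot anchor a read uniquely
    core = "ACGCGT"  # rc(ACGCGT) == ACGCGT
    assert revcomp(core) == core
    seq = "TTGGCC" + core + "GGTTCC"
    g = build_graph([seq], 6)
    hits = find_seeds(_read(seq), g)
    assert all(seq[h.read_offset : h.read_offset + 6] != core for h in hits)


def test_error_free_read_is_reproduced_identically(locus):
    genome, g = locus
    read = _read(genome[40:140])
    res = extend_alignment(read, find_seeds(read, g), g)
    assert res.status == "corrected"
    assert res.corrected_seq == read.seq
    assert res.identity == 1.0


def test_substitutions_are_replaced_by_graph_consensus(locus):
    genome, g = locus
    true = genome[40:140]
    for pos in (2, 50, 97):  # near both ends and the middle
        read = _read(_mutate(true, pos))
        res = extend_alignment(read, find_seeds(read, g), g)
        assert res.corrected_seq == true, f"substitution at {pos}"
        assert res.identity >= 0.97


def test_reverse_complement_read_corrected_in_its_own_orientation(locus):
    genome, g = locus
    true = genome[40:140]
    read = _read(revcomp(_mutate(true, 30)))
    res = extend_alignment(read, find_seeds(read, g), g)
    assert res.corrected_seq == revcomp(true)


def test_corrected_base_keeps_quality_and_length(locus):
    genome, g = locus
    true = genome[40:140]
    qual = "".join(chr(33 + (i % 40)) for i in range(100))
    read = _read(_mutate(true, 55), qual)
    res = extend_alignment(read, find_seeds(read, g), g)
    assert res.corrected_seq == true
    assert res.corrected_qual == qual  # substitution keeps the base quality


def test_fork_resolved_by_read_content(rng):
    shared = random_seq(rng, 100)
    bra = random_seq(rng, 100)
    brb = random_seq(rng, 100)
    reads_a = [(shared + bra)[i : i + 100] for i in range(0, 101, 5)]
    reads_b = [(shared + brb)[i : i + 100] for i in range(0, 101, 5)]
    g = build_graph(reads_a + reads_b, 15)
    assert len(g.nodes) == 3
    query = (shared + bra)[60:160]
    res = extend_alignment(_read(query), find_seeds(_read(query), g), g)
    assert res.corrected_seq == query


def test_cluster_correction_statuses_and_foreign_read(rng):
    genome = random_seq(rng, 300)
    clean_reads = [
        ReadRecord(f"c{i}", genome[s : s + 100], "I" * 100, 1)
        for i, s in enumerate(list(range(0, 201, 10)) * 2)
    ]
    bad = ReadRecord("bad", _mutate(genome[100:200], 50), "I" * 100, 1)
    foreign = ReadRecord("alien", random_seq(rng, 100), "I" * 100, 1)
    g = clean_graph(
        build_graph(clean_reads + [bad], 15),
        CleanParams(max_error_node_len=85, cutoff=10.0),
    )
    results = correct_cluster(clean_reads + [bad, foreign], g)
    assert all(
        results[i].status == "corrected" and results[i].corrected_seq == r.seq
        for i, r in enumerate(clean_reads)
    )
    assert results[len(clean_reads)].corrected_seq == genome[100:200]
    assert results[len(clean_reads) + 1].status == "unaligned"
    assert results[len(clean_reads) + 1].corrected_seq == foreign.seq


def test_correction_is_idempotent(rng):
    genome = random_seq(rng, 300)
    reads = [ReadRecord(f"c{i}", genome[i * 10 : i * 10 + 100] if False else genome[s : s + 100], "I" * 100, 1)
             for i, s in enumerate(range(0, 201, 10))]
    noisy = [ReadRecord(r.id, _mutate(r.seq, 40), r.qual, 1) for r in reads[:5]] + list(reads[5:])
    g = clean_graph(build_graph(noisy * 3, 15), CleanParams(max_error_node_len=85, cutoff=4.0))
    first = correct_cluster(noisy, g)
    once = [ReadRecord(r.id, first[i].corrected_seq, first[i].corrected_qual, 1)
            for i, r in enumerate(noisy)]
    second = correct_cluster(once, g)
    assert all(second[i].corrected_seq == once[i].seq for i in range(len(once)))


def test_corrected_sequences_are_spelled_by_graph_paths(rng):
    genome = random_seq(rng, 400)
    reads = [ReadRecord(f"c{i}", genome[s : s + 100], "I" * 100, 1)
             for i, s in enumerate(range(0, 301, 10))]
    g = build_graph(reads, 15)
    results = correct_cluster(reads, g)
    for res in results.values():
        if res.status != "corrected" or not res.path:
            continue
        # re-walk the path: spelled sequence must contain the correction
        nid, ori = res.path[0]
        spelled = g.oriented_seq(nid, ori)
        for nid, ori in res.path[1:]:
            spelled += g.oriented_seq(nid, ori)[g.k - 1 :]
        assert res.corrected_seq in spelled


def test_exhausted_search_budget_leaves_read_unchanged(rng):
    # a fork forces the DFS to visit successor nodes; budget 0 aborts
    shared = random_seq(rng, 100)
    bra, brb = random_seq(rng, 100), random_seq(rng, 100)
    reads = [(shared + br)[i : i + 100] for br in (bra, brb) for i in range(0, 101, 5)]
    g = build_graph(reads, 15)
    query = _read((shared + bra)[60:160])
    ok = extend_alignment(query, find_seeds(query, g), g)
    assert ok.status == "corrected"
    aborted = extend_alignment(query, find_seeds(query, g), g, GraphAlignParams(max_branch=0))
    assert aborted.status == "unchanged"
    assert aborted.corrected_seq == query.seq
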