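"""De Bruijn graph construction, the two-Poisson EM coverage model, and
conservative tip/bubble cleaning."""

import numpy as np
import pytest

from polycor.dbg import (
    CleanParams,
    ModelError,
    build_graph,
    clean_graph,
    detect_erroneous_nodes,
    fit_coverage_model,
    poisson_intersection,
    write_gfa,
)
from polycor.kmers import revcomp
from .conftest import random_seq


def test_two_overlapping_reads_contract_to_one_unitig():
    g = build_graph(["ACGGT", "CGGTA"], 3)
    assert len(g.nodes) == 1
    node = next(iter(g.nodes.values()))
    assert node.seq == "ACGGTA"
    assert node.length == 4
    assert node.avg_cov == pytest.approx((1 + 2 + 2 + 1) / 4)


def test_single_read_without_rc_collisions_is_one_unitig():
    seq = "ACCAGTTCGA"
    g = build_graph([seq], 5)
    assert len(g.nodes) == 1
    node = next(iter(g.nodes.values()))
    assert node.seq in (seq, revcomp(seq))
    assert node.avg_cov == 1.0


def test_error_free_tiling_reads_rebuild_the_genome(rng):
    genome = random_seq(rng, 500)
    reads = [genome[i : i + 60] for i in range(0, 441, 15)] + [genome[440:]]
    g = build_graph(reads, 15)
    assert len(g.nodes) == 1
    node = next(iter(g.nodes.values()))
    assert node.seq in (genome, revcomp(genome))


def test_kmer_mass_is_conserved(rng):
    reads = [random_seq(rng, 80) for _ in range(30)]
    g = build_graph(reads, 15)
    windows = sum(len(r) - 15 + 1 for r in reads)
    assert g.total_kmer_mass() == pytest.approx(windows)


def test_k_larger_than_read_rejected():
    with pytest.raises(ValueError):
        build_graph(["ACGT"], 5)


# -- coverage model ----------------------------------------------------


def test_cutoff_matches_closed_form_crossing():
    # equal weights, lambda_e=2, lambda_c=30: crossing at 28/ln(15)
    assert poisson_intersection(2, 30, 0.5, 0.5) == pytest.approx(28 / np.log(15), abs=1e-9)
    # asymmetric weights shift the crossing
    assert poisson_intersection(2, 30, 0.8, 0.2) == pytest.approx(
        (28 + np.log(4)) / np.log(15), abs=1e-9
    )


def test_em_recovers_mixture_within_15_percent(rng):
    draws = np.concatenate([rng.poisson(2, 1000), rng.poisson(30, 1000)]).astype(float)
    model = fit_coverage_model([(d, 1.0) for d in draws])
    assert model.lambda_e == pytest.approx(2.0, rel=0.15)
    assert model.lambda_c == pytest.approx(30.0, rel=0.15)
    assert model.w_e == pytest.approx(0.5, abs=0.1)
    assert model.cutoff == pytest.approx(
        poisson_intersection(model.lambda_e, model.lambda_c, model.w_e, model.w_c),
        abs=1e-6,
    )
    assert model.lambda_e < model.cutoff < model.lambda_c


def test_em_loglikelihood_never_decreases(rng):
    draws = np.concatenate([rng.poisson(3, 300), rng.poisson(20, 300)]).astype(float)
    lls = []
    for iters in range(1, 12):
        m = fit_coverage_model([(d, 1.0) for d in draws], max_iter=iters, tol=0.0)
        lls.append(m.log_likelihood)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_degenerate_coverage_data_raises_model_error():
    with pytest.raises(ModelError):
        fit_coverage_model([(5.0, 1.0)] * 50)
    with pytest.raises(ModelError):
        fit_coverage_model([(1.0, 1.0)] * 5)


# -- cleaning ----------------------------------------------------------


def _tiling_reads(seq, l=40, step=5):
    return [seq[i : i + l] for i in range(0, len(seq) - l + 1, step)]


def test_linear_chain_has_no_erroneous_nodes(rng):
    genome = random_seq(rng, 300)
    g = build_graph(_tiling_reads(genome) * 3, 15)
    params = CleanParams(max_error_node_len=25, cutoff=10.0)
    assert detect_erroneous_nodes(g, params) == set()
    cleaned = clean_graph(g, params)
    assert sorted(n.seq for n in cleaned.nodes.values()) == sorted(
        n.seq for n in g.nodes.values()
    )


def test_low_coverage_tip_is_flagged_and_removed(rng):
    genome = random_seq(rng, 200)
    reads = _tiling_reads(genome) * 20
    # one read wanders off mid-genome: creates a dead-end branch
    tip_read = genome[80:100] + random_seq(rng, 20)
    g = build_graph(reads + [tip_read], 15)
    assert len(g.nodes) > 1
    params = CleanParams(max_error_node_len=30, cutoff=10.0)
    flagged = detect_erroneous_nodes(g, params)
    assert flagged
    assert all(g.nodes[nid].avg_cov < 10.0 for nid in flagged)
    cleaned = clean_graph(g, params)
    assert len(cleaned.nodes) == 1
    node = next(iter(cleaned.nodes.values()))
    assert node.seq in (genome, revcomp(genome))


def test_bubble_low_coverage_branch_removed_high_kept(rng):
    genome = random_seq(rng, 200)
    mutant = genome[:100] + ("A" if genome[100] != "A" else "C") + genome[101:]
    reads = _tiling_reads(genome) * 18 + _tiling_reads(mutant) * 2
    g = build_graph(reads, 15)
    params = CleanParams(max_error_node_len=30, cutoff=30.0)
    cleaned = clean_graph(g, params)
    assert len(cleaned.nodes) == 1
    node = next(iter(cleaned.nodes.values()))
    assert node.seq in (genome, revcomp(genome))


def test_error_free_graph_is_clean_fixpoint(rng):
    genome = random_seq(rng, 400)
    g = build_graph(_tiling_reads(genome) * 10, 15)
    params = CleanParams(max_error_node_len=25, cutoff=5.0)
    cleaned = clean_graph(g, params)
    assert sorted(n.seq for n in cleaned.nodes.values()) == sorted(
        n.seq for n in g.nodes.values()
    )


def test_single_end_substitution_cleaned_to_single_unitig(rng):
    genome = random_seq(rng, 200)
    bad = list(genome[100:140])
    bad[2] = "A" if bad[2] != "A" else "C"
    reads = _tiling_reads(genome) * 20 + ["".join(bad)]
    g = build_graph(reads, 15)
    cleaned = clean_graph(g, CleanParams(max_error_node_len=25, cutoff=10.0))
    assert len(cleaned.nodes) == 1
    assert next(iter(cleaned.nodes.values())).seq in (genome, revcomp(genome))


def test_nested_errors_resolved_across_rounds(rng):
    genome = random_seq(rng, 200)
    # a bubble branch that itself carries a dangling tip
    mutant = genome[:100] + ("A" if genome[100] != "A" else "C") + genome[101:120]
    tip = mutant[90:121] + random_seq(rng, 10)
    reads = _tiling_reads(genome) * 20 + _tiling_reads(mutant, l=30, step=4) * 2 + [tip]
    g = build_graph(reads, 15)
    cleaned = clean_graph(g, CleanParams(max_error_node_len=30, cutoff=10.0, max_rounds=10))
    assert len(cleaned.nodes) == 1
    assert next(iter(cleaned.nodes.values())).seq in (genome, revcomp(genome))


def test_gfa_export_lists_all_unitigs(rng, tmp_path):
    genome = random_seq(rng, 150)
    g = build_graph(_tiling_reads(genome) * 2, 15)
    path = tmp_path / "graph.gfa"
    write_gfa(g, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("H")
    assert sum(1 for l in lines if l.startswith("S")) == len(g.nodes)
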