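"""End-to-end targeted correction: extract -> cluster -> correct -> merge.

Only read pairs containing the repetitive pattern are touched; everything
else passes through byte-identical.  Extracted pairs are clustered into
per-locus groups, each cluster's reads are corrected against its own
cleaned de Bruijn graph, and corrected pairs are substituted back by
ordinal, so output order and record count always equal the input.  The
whole run is deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import cluster as _cluster
from . import dbg as _dbg
from . import graphalign as _ga
from .kmers import RepetitivePattern, count_kmers, extract_pairs, homopolymer_runs, canonical
from .seqio import ReadPair, ReadRecord, merge_corrected, read_paired_fastq, write_paired_fastq

__all__ = ["PipelineConfig", "RunReport", "run_correct", "correct_pairs"]

log = logging.getLogger("polycor")


@dataclass
class PipelineConfig:
    """All pipeline knobs with the defaults used throughout.

    tau defaults to 0.4 * read length when left unset; max_error_node_len
    defaults to avgReadLen - dbg_k.  c_k, when None, is estimated from the
    extracted reads (75th percentile of non-repeat k-mer counts).
    """

    pattern_kind: str = "polyAT"
    pattern_k: int = 15
    cluster_k: int = 15
    dbg_k: int = 15
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -3.0
    tau: Optional[float] = None
    beta: float = 2.0
    c_k: Optional[float] = None
    n_runs: int = 20
    theta: float = 0.8
    min_cluster_size: int = 5
    max_error_node_len: Optional[int] = None
    cutoff: Optional[float] = None
    max_rounds: int = 10
    min_identity: float = 0.8
    max_branch: int = 1000
    seed: int = 0
    threads: int = 1

    def pattern(self) -> RepetitivePattern:
        if self.pattern_kind in ("polyAT", "polyCG"):
            return RepetitivePattern(kind=self.pattern_kind, k=self.pattern_k)
        return RepetitivePattern(
            kind="explicit", k=len(self.pattern_kind), explicit_seq=self.pattern_kind
        )


@dataclass
class RunReport:
    """Machine-readable run summary."""

    total_pairs: int = 0
    extracted_pairs: int = 0
    n_clusters: int = 0
    core_pairs: int = 0
    unassigned_pairs: int = 0
    reads_corrected: int = 0
    reads_unchanged: int = 0
    reads_unaligned: int = 0
    modified_pairs: int = 0
    fraction_modified: float = 0.0
    cluster_sizes: list[int] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as h:
            json.dump(asdict(self), h, indent=2)


def _estimate_ck(selected, counts, pattern) -> float:
    """Data-driven stand-in for the expected extracted coverage C_k: the
    75th percentile of counts of k-mers outside the homopolymer run."""
    vals = []
    k = counts.k
    for pair in selected:
        for rec in (pair.r1, pair.r2):
            runs = homopolymer_runs(rec.seq, pattern.bases, pattern.k)
            for i in range(len(rec.seq) - k + 1):
                if any(i < e and i + k > s for s, e in runs):
                    continue
                w = rec.seq[i : i + k]
                if "N" not in w:
                    vals.append(counts.get(w))
    if not vals:
        return 1.0
    return float(max(np.percentile(vals, 75), 1.0))


def correct_pairs(cfg: PipelineConfig, pairs: list[ReadPair]) -> tuple[list[ReadPair], RunReport, dict]:
    """Run the correction pipeline on in-memory pairs.

    Returns (corrected pair list, report, debug artifacts).  The debug
    dict holds the similarity graph, stable cores and per-cluster graphs
    for optional dumping.
    """
    report = RunReport(total_pairs=len(pairs))
    debug: dict = {}
    t0 = time.perf_counter()

    pattern = cfg.pattern()
    selected, passthrough = extract_pairs(pairs, pattern)
    report.extracted_pairs = len(selected)
    report.timings["extract"] = time.perf_counter() - t0
    log.info("extracted %d of %d pairs", len(selected), len(pairs))
    if not selected:
        return list(pairs), report, debug

    read_len = int(np.mean([len(p.r1.seq) for p in selected]))
    tau = cfg.tau if cfg.tau is not None else 0.4 * read_len
    align_params = _cluster.AlignScoreParams(
        match=cfg.match, mismatch=cfg.mismatch, gap=cfg.gap, tau=tau
    )

    t1 = time.perf_counter()
    counts = count_kmers(
        [p.r1 for p in selected] + [p.r2 for p in selected], cfg.cluster_k
    )
    c_k = cfg.c_k if cfg.c_k is not None else _estimate_ck(selected, counts, pattern)
    log.info("C_k = %.1f", c_k)
    sim_graph = _cluster.build_similarity_graph(
        selected, counts, c_k, align_params, beta=cfg.beta, pattern=pattern
    )
    report.timings["similarity_graph"] = time.perf_counter() - t1
    log.info(
        "similarity graph: %d nodes, %d edges",
        sim_graph.number_of_nodes(),
        sim_graph.number_of_edges(),
    )

    t2 = time.perf_counter()
    cores = _cluster.stable_cores(
        sim_graph, n_runs=cfg.n_runs, theta=cfg.theta, seed=cfg.seed
    )
    report.timings["clustering"] = time.perf_counter() - t2
    debug["similarity_graph"] = sim_graph
    debug["cores"] = cores

    by_ordinal = {p.ordinal: p for p in selected}
    corrected: dict[int, ReadPair] = {}
    ga_params = _ga.GraphAlignParams(
        match=cfg.match,
        mismatch=cfg.mismatch,
        gap=cfg.gap,
        min_identity=cfg.min_identity,
        max_branch=cfg.max_branch,
    )
    debug["cluster_graphs"] = []

    t3 = time.perf_counter()
    usable = [core for core in cores.cores if len(core) >= cfg.min_cluster_size]
    small = [core for core in cores.cores if len(core) < cfg.min_cluster_size]
    report.n_clusters = len(usable)
    report.core_pairs = sum(len(c) for c in usable)
    report.unassigned_pairs = len(cores.unassigned) + sum(len(c) for c in small)
    report.cluster_sizes = sorted((len(c) for c in usable), reverse=True)

    for core in usable:
        ordinals = sorted(core)
        reads: list[ReadRecord] = []
        for o in ordinals:
            reads.append(by_ordinal[o].r1)
            reads.append(by_ordinal[o].r2)
        graph = _dbg.build_graph(reads, cfg.dbg_k)
        max_len = (
            cfg.max_error_node_len
            if cfg.max_error_node_len is not None
            else max(read_len - cfg.dbg_k, 1)
        )
        if cfg.cutoff is not None:
            cutoff = cfg.cutoff
        else:
            try:
                model = _dbg.fit_coverage_model(graph.node_coverages())
                cutoff = model.cutoff
            except _dbg.ModelError:
                covs = [c for c, _ in graph.node_coverages()]
                cutoff = max(2.0, float(np.mean(covs)) / 4.0)
            cutoff = _dbg.cap_cutoff(graph, cutoff, max_len)
        clean = _dbg.clean_graph(
            graph,
            _dbg.CleanParams(max_error_node_len=max_len, cutoff=cutoff, max_rounds=cfg.max_rounds),
        )
        debug["cluster_graphs"].append((ordinals, clean))
        results = _ga.correct_cluster(reads, clean, ga_params)
        for res in results.values():
            if res.status == "corrected":
                report.reads_corrected += 1
            elif res.status == "unchanged":
                report.reads_unchanged += 1
            else:
                report.reads_unaligned += 1
        for idx, o in enumerate(ordinals):
            pair = by_ordinal[o]
            res1, res2 = results[2 * idx], results[2 * idx + 1]
            new1 = (
                ReadRecord(pair.r1.id, res1.corrected_seq, res1.corrected_qual, 1)
                if res1.status == "corrected"
                else pair.r1
            )
            new2 = (
                ReadRecord(pair.r2.id, res2.corrected_seq, res2.corrected_qual, 2)
                if res2.status == "corrected"
                else pair.r2
            )
            corrected[o] = ReadPair(ordinal=o, r1=new1, r2=new2)
    report.timings["correction"] = time.perf_counter() - t3

    merged = merge_corrected(pairs, corrected)
    report.modified_pairs = sum(
        1
        for orig, new in zip(pairs, merged)
        if (orig.r1.seq, orig.r2.seq, orig.r1.qual, orig.r2.qual)
        != (new.r1.seq, new.r2.seq, new.r1.qual, new.r2.qual)
    )
    report.fraction_modified = (
        report.modified_pairs / report.total_pairs if report.total_pairs else 0.0
    )
    report.timings["total"] = time.perf_counter() - t0
    return merged, report, debug


def run_correct(
    cfg: PipelineConfig,
    in1,
    in2,
    out1,
    out2,
    *,
    interleaved: bool = False,
    debug_dir: Optional[str] = None,
) -> RunReport:
    """File-level pipeline entry point.

    Reads paired FASTQ, corrects, and writes paired FASTQ preserving
    record order and count.  With ``debug_dir`` set, intermediate
    artifacts (edge list, cluster map, per-cluster GFA) are dumped there.
    """
    pairs = read_paired_fastq(in1, in2, interleaved=interleaved)
    merged, report, debug = correct_pairs(cfg, pairs)
    write_paired_fastq(merged, out1, out2)

    if debug_dir is not None:
        d = Path(debug_dir)
        d.mkdir(parents=True, exist_ok=True)
        if "similarity_graph" in debug:
            _cluster.write_edge_list(debug["similarity_graph"], d / "edges.tsv")
            _cluster.write_clusters(debug["cores"], d / "clusters.tsv")
            for i, (ordinals, graph) in enumerate(debug.get("cluster_graphs", [])):
                _dbg.write_gfa(graph, d / f"cluster_{i}.gfa")
        report.to_json(d / "report.json")
    return report
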