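"""Read-pair similarity graph and community detection.

Extracted read pairs are clustered so that each cluster holds pairs from a
single genomic locus.  Similarity between two pairs combines the overlap
alignment score of the repeat-containing reads with that of their mates:
mate overlap is what separates loci that share nothing but the homopolymer
itself.  The similarity graph is kept sparse by only scoring pairs that
share at least one non-repeated k-mer (count at most beta * C_k, outside
the homopolymer run).  Louvain community detection, repeated with distinct
seeds, yields stable core clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities
from networkx.algorithms.community import modularity as nx_modularity

from .kmers import KmerCountTable, RepetitivePattern, homopolymer_runs, revcomp
from .seqio import ReadPair, ReadRecord

__all__ = [
    "AlignScoreParams",
    "Partition",
    "StableCores",
    "overlap_align_score",
    "pair_similarity",
    "build_similarity_graph",
    "louvain",
    "stable_cores",
    "write_edge_list",
    "write_clusters",
]


@dataclass(frozen=True)
class AlignScoreParams:
    """Overlap-alignment scoring and the edge-creation threshold tau.

    Defaults (+1/-1/-3 linear, tau = 40 for 100 bp reads) demand roughly a
    40 bp confident overlap before two pairs are considered similar.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -3.0
    tau: float = 40.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap > 0 or self.tau <= 0:
            raise ValueError("require match > 0, mismatch <= 0, gap <= 0, tau > 0")


def _seq_codes(s: str) -> np.ndarray:
    # 'N' mapped to a sentinel that never equals anything (incl. itself)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0
    return arr


def _suffix_prefix_best(a: np.ndarray, b: np.ndarray, p: AlignScoreParams) -> float:
    """Best global alignment score of any suffix of a against any prefix of b.

    DP with a free first column (suffix start in a) and the maximum taken
    over the last row (prefix end in b).  Linear gap costs allow the
    in-row dependency to be resolved with a prefix-scan.
    """
    n = b.size
    jg = p.gap * np.arange(n + 1)
    prev = jg.copy()  # row 0: empty suffix of a vs b prefix -> leading gaps in a... cost j*gap
    for i in range(a.size):
        s = np.where((b == a[i]) & (a[i] != 0), p.match, p.mismatch)
        diag = prev[:-1] + s
        up = prev[1:] + p.gap
        m = np.maximum(diag, up)
        # cur[0] is a fresh free start (skip a[:i+1]); left-gap closure by scan
        cand = np.concatenate(([0.0], m)) - jg
        prev = np.maximum.accumulate(cand) + jg
        prev[0] = 0.0
    return float(prev.max())


def overlap_align_score(a: str, b: str, p: AlignScoreParams) -> float:
    """Overlap alignment score with free end gaps.

    The maximum of (i) the best suffix-of-a vs prefix-of-b global alignment,
    (ii) the best suffix-of-b vs prefix-of-a global alignment and (iii) the
    empty overlap (score 0); hence always >= 0.  Gaps *inside* the overlap
    are penalized normally; only the non-overlapping leading/trailing ends
    are free.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ca, cb = _seq_codes(a), _seq_codes(b)
    return max(_suffix_prefix_best(ca, cb, p), _suffix_prefix_best(cb, ca, p), 0.0)


def _rc_pair(pair: ReadPair) -> ReadPair:
    """Reverse complement a pair as a unit: the fragment flips, so mates
    swap roles and each is reverse complemented."""
    return ReadPair(
        ordinal=pair.ordinal,
        r1=ReadRecord(pair.r2.id, revcomp(pair.r2.seq), pair.r2.qual[::-1], 1),
        r2=ReadRecord(pair.r1.id, revcomp(pair.r1.seq), pair.r1.qual[::-1], 2),
    )


def pair_similarity(a: ReadPair, b: ReadPair, p: AlignScoreParams) -> float:
    """Similarity between two read pairs.

    Maximum over the two mate matchings (r1<->r1 + r2<->r2, and
    r1<->r2 + r2<->r1), each evaluated with b as-is and with b reverse
    complemented as a unit, of the summed overlap alignment scores.
    Symmetric in its arguments.
    """
    a1, a2 = _seq_codes(a.r1.seq), _seq_codes(a.r2.seq)
    best = 0.0
    for bv in (b, _rc_pair(b)):
        b1, b2 = _seq_codes(bv.r1.seq), _seq_codes(bv.r2.seq)
        for x1, x2 in ((b1, b2), (b2, b1)):
            s = max(_suffix_prefix_best(a1, x1, p), _suffix_prefix_best(x1, a1, p), 0.0)
            s += max(_suffix_prefix_best(a2, x2, p), _suffix_prefix_best(x2, a2, p), 0.0)
            best = max(best, s)
    return best


def _filter_kmers(
    pair: ReadPair, k: int, pattern: Optional[RepetitivePattern]
) -> set[str]:
    """Canonical k-mers of both mates excluding windows that overlap a
    homopolymer run of the repetitive pattern."""
    from .kmers import canonical

    out: set[str] = set()
    for rec in (pair.r1, pair.r2):
        seq = rec.seq
        runs = (
            homopolymer_runs(seq, pattern.bases, pattern.k)
            if pattern is not None and pattern.bases
            else []
        )
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            if any(i < e and i + k > s for s, e in runs):
                continue
            out.add(canonical(w))
    return out


def build_similarity_graph(
    selected: Sequence[ReadPair],
    counts: KmerCountTable,
    c_k: float,
    p: AlignScoreParams,
    *,
    beta: float = 2.0,
    pattern: Optional[RepetitivePattern] = None,
) -> nx.Graph:
    """Build the weighted similarity graph over extracted pair ordinals.

    Candidate node pairs are those sharing at least one non-repeated k-mer:
    a k-mer with count <= beta * C_k that does not overlap the detected
    homopolymer run.  An edge is created iff pair_similarity >= tau.  The
    graph is generally very sparse because the prefilter discards pair
    combinations with apparent low sequence similarity.
    """
    if c_k <= 0:
        raise ValueError("C_k must be positive")
    g = nx.Graph()
    g.add_nodes_from(pair.ordinal for pair in selected)
    by_ordinal = {pair.ordinal: pair for pair in selected}

    threshold = beta * c_k
    buckets: dict[str, list[int]] = {}
    for pair in selected:
        for w in _filter_kmers(pair, counts.k, pattern):
            if counts.get(w) <= threshold:
                buckets.setdefault(w, []).append(pair.ordinal)

    candidates: set[tuple[int, int]] = set()
    for members in buckets.values():
        members.sort()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                candidates.add((members[i], members[j]))

    for u, v in sorted(candidates):
        w = pair_similarity(by_ordinal[u], by_ordinal[v], p)
        if w >= p.tau:
            g.add_edge(u, v, weight=w)
    return g


@dataclass
class Partition:
    """A community assignment (node -> community id) and its modularity."""

    assignment: dict[int, int]
    modularity: float

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return [out[cid] for cid in sorted(out)]


def louvain(g: nx.Graph, seed: int) -> Partition:
    """Louvain community detection (greedy modularity maximization).

    Deterministic for a given seed.  Community ids are assigned in order of
    each community's smallest node so that identical clusterings compare
    equal regardless of internal ordering.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comms = louvain_communities(g, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    assignment = {node: cid for cid, members in enumerate(comms) for node in members}
    if g.number_of_edges() == 0:
        q = 0.0
    else:
        q = nx_modularity(g, [set(c) for c in comms], weight="weight")
    return Partition(assignment=assignment, modularity=q)


@dataclass
class StableCores:
    """Cross-run consensus clusters: disjoint cores plus unassigned nodes."""

    cores: list[set[int]]
    unassigned: set[int]
    n_runs: int = 20
    theta: float = 0.8


def stable_cores(
    g: nx.Graph, n_runs: int = 20, theta: float = 0.8, seed: int = 0
) -> StableCores:
    """Stable core communities across repeated randomized Louvain runs.

    Two nodes belong to the same core iff they were co-clustered in at
    least theta * n_runs runs; cores are the connected components of that
    co-clustering relation.  A node consistently placed in a singleton
    community forms a singleton core; nodes with no stable affiliation are
    left unassigned (and pass through the pipeline uncorrected).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_runs)]

    nodes = sorted(g.nodes)
    co: dict[tuple[int, int], int] = {}
    alone: dict[int, int] = {node: 0 for node in nodes}
    for rs in run_seeds:
        part = louvain(g, seed=rs)
        for comm in part.communities():
            members = sorted(comm)
            if len(members) == 1:
                alone[members[0]] += 1
                continue
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    key = (members[i], members[j])
                    co[key] = co.get(key, 0) + 1

    need = theta * n_runs - 1e-9
    h = nx.Graph()
    h.add_nodes_from(nodes)
    for (u, v), c in co.items():
        if c >= need:
            h.add_edge(u, v)

    cores: list[set[int]] = []
    unassigned: set[int] = set()
    for comp in nx.connected_components(h):
        if len(comp) > 1:
            cores.append(set(comp))
        elif alone[next(iter(comp))] >= need:
            cores.append(set(comp))
        else:
            unassigned.add(next(iter(comp)))
    cores.sort(key=min)
    return StableCores(cores=cores, unassigned=unassigned, n_runs=n_runs, theta=theta)


def write_edge_list(g: nx.Graph, path) -> None:
    """Tab-separated edge dump (node_a, node_b, weight) for debugging."""
    with open(path, "w") as h:
        for u, v, data in sorted(g.edges(data=True)):
            h.write(f"{u}\t{v}\t{data['weight']:g}\n")


def write_clusters(cores: StableCores, path) -> None:
    """Tab-separated cluster assignment (ordinal, cluster_id); unassigned
    nodes get cluster id -1."""
    with open(path, "w") as h:
        for cid, core in enumerate(cores.cores):
            for node in sorted(core):
                h.write(f"{node}\t{cid}\n")
        for node in sorted(cores.unassigned):
            h.write(f"{node}\t-1\n")
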