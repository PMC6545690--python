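"""Seed-and-extend alignment of reads to a cleaned de Bruijn graph.

Each read's error-free k-mers anchor it uniquely to a unitig; the read is
then extended left and right of the anchored region by a depth-first
search over the graph, with branch-and-bound pruning of path candidates
that can no longer beat the current best alignment.  The best-scoring
path spells the corrected read: mismatches and indels in the read are
replaced by the graph's consensus sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dbg import DeBruijnGraph
from .kmers import canonical, revcomp
from .seqio import ReadRecord

__all__ = [
    "SeedHit",
    "AlignmentResult",
    "GraphAlignParams",
    "find_seeds",
    "extend_alignment",
    "correct_cluster",
]


@dataclass(frozen=True)
class SeedHit:
    """A read k-mer uniquely anchored in the graph.

    ``strand`` '+' means the read k-mer equals the node k-mer at
    ``node_offset`` in the node's stored orientation; '-' means it equals
    its reverse complement.
    """

    read_offset: int
    node: int
    node_offset: int
    strand: str


@dataclass
class AlignmentResult:
    """Outcome of aligning one read to the graph.

    ``corrected_seq`` is spelled exactly by ``path`` (a list of oriented
    unitigs); ``status`` is 'corrected' when the alignment met the
    identity threshold, 'unchanged' when it did not (or the search
    aborted), and 'unaligned' when no seed anchored the read.
    """

    path: list[tuple[int, str]]
    corrected_seq: str
    corrected_qual: str
    score: float
    identity: float
    status: str


@dataclass(frozen=True)
class GraphAlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -3.0
    min_identity: float = 0.8
    max_branch: int = 1000
    slack: int = 8  # extra graph bases explored beyond the read end


class _SearchAborted(Exception):
    pass


def find_seeds(read: ReadRecord, g: DeBruijnGraph) -> list[SeedHit]:
    """Seeds for read k-mers occurring exactly once in the graph (counting
    both strands), in read order.  Self-reverse-complement k-mers occur on
    both strands at once and are excluded as ambiguous."""
    k = g.k
    seq = read.seq
    hits: list[SeedHit] = []
    for off in range(len(seq) - k + 1):
        w = seq[off : off + k]
        if "N" in w:
            continue
        if w == revcomp(w):
            continue
        hit = g.lookup_kmer(w)
        if hit is None:
            continue
        nid, noff, _ = hit
        node_w = g.nodes[nid].seq[noff : noff + k]
        strand = "+" if node_w == w else "-"
        hits.append(SeedHit(read_offset=off, node=nid, node_offset=noff, strand=strand))
    return hits


def _anchored_dp(query: str, ref: str, p: GraphAlignParams) -> np.ndarray:
    """DP matrix for aligning the full query against a prefix of ref
    (ref end free via max over the last row, taken by callers)."""
    m, n = len(query), len(ref)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    nmask = ord("N")
    H = np.empty((m + 1, n + 1))
    jg = p.gap * np.arange(n + 1)
    H[0] = jg
    for i in range(1, m + 1):
        s = np.where((r == q[i - 1]) & (q[i - 1] != nmask) & (r != nmask), p.match, p.mismatch)
        mdag = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + p.gap)
        cand = np.concatenate(([p.gap * i], mdag)) - jg
        H[i] = np.maximum.accumulate(cand) + jg
    return H


def _traceback(
    query: str, ref: str, H: np.ndarray, p: GraphAlignParams
) -> tuple[float, int, int, list[str], int, int]:
    """Best alignment endpoint and its path back to the anchor.

    Returns (score, query_end, ref_end, ops, matches, columns).  The
    alignment either consumes the full query (endpoint on the last row,
    ref end free) or consumes the full ref with query left over (endpoint
    on the last column): the leftover query overhang is the part of the
    read a dead-ended graph path cannot spell and is kept verbatim by
    the caller.  ops are 'M' (both advance), 'I' (ref only: base
    inserted into the corrected read), 'D' (query only: read base
    dropped), ordered from the anchor outward.
    """
    m, n = len(query), len(ref)
    j_best = int(np.argmax(H[m]))
    i_best = int(np.argmax(H[:, n]))
    if H[m, j_best] >= H[i_best, n]:
        i, j = m, j_best
    else:
        i, j = i_best, n
    score = float(H[i, j])
    end_i, end_j = i, j
    ops: list[str] = []
    matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            eq = query[i - 1] == ref[j - 1] and query[i - 1] != "N" and ref[j - 1] != "N"
            s = p.match if eq else p.mismatch
            if np.isclose(H[i, j], H[i - 1, j - 1] + s):
                ops.append("M")
                matches += int(eq)
                i -= 1
                j -= 1
                continue
        if i > 0 and np.isclose(H[i, j], H[i - 1, j] + p.gap):
            ops.append("D")
            i -= 1
            continue
        ops.append("I")
        j -= 1
    ops.reverse()
    return score, end_i, end_j, ops, matches, len(ops)


def _extend_side(
    g: DeBruijnGraph,
    node: int,
    ori: str,
    pos: int,
    query: str,
    p: GraphAlignParams,
    budget: list[int],
) -> tuple[float, str, list[str], int, int, str, list[tuple[int, str]]]:
    """DFS + branch-and-bound extension of ``query`` along graph paths
    starting at offset ``pos`` of oriented unitig (node, ori).

    Returns (score, ref_segment, ops, matches, columns, overhang,
    extra_path) for the best-scoring path, where ``overhang`` is the query
    suffix beyond the graph's reach (kept uncorrected by the caller);
    raises _SearchAborted when the node-visit budget is exhausted.
    """
    if not query:
        return 0.0, "", [], 0, 0, "", []
    needed = len(query) + p.slack
    start_ref = g.oriented_seq(node, ori)[pos:]
    best: Optional[tuple[float, str, list[str], int, int, str, list[tuple[int, str]]]] = None

    def finalize(ref: str, path: list[tuple[int, str]]) -> None:
        nonlocal best
        H = _anchored_dp(query, ref, p)
        score, iend, jend, ops, matches, cols = _traceback(query, ref, H, p)
        cand = (score, ref[:jend], ops, matches, cols, query[iend:], path)
        if best is None or score > best[0]:
            best = cand

    def dfs(cur: tuple[int, str], ref: str, path: list[tuple[int, str]]) -> None:
        nonlocal best
        if len(ref) >= needed:
            finalize(ref, path)
            return
        succs = g.adj.get(cur, [])
        if not succs:
            finalize(ref, path)
            return
        dead_end = True
        for nxt in succs:
            appended = g.oriented_seq(*nxt)[g.k - 1 :]
            if nxt == cur:
                # a self-loop (homopolymer run >= k collapses to one node
                # with a self-arc) can spin out run bases forever; it is
                # only worth another turn while the read still reads the
                # run, otherwise the graph has nothing new to spell
                pos = len(ref)
                if query[pos : pos + len(appended)] != appended:
                    continue
            dead_end = False
            budget[0] -= 1
            if budget[0] < 0:
                raise _SearchAborted
            ext = ref + appended
            if best is not None:
                H = _anchored_dp(query, ext[: needed], p)
                # optimistic completion: best cell plus perfect matches for
                # the unconsumed query suffix
                mrange = np.arange(len(query) + 1)
                bound = float(np.max(H.max(axis=1) + (len(query) - mrange) * p.match))
                if bound <= best[0]:
                    continue
            dfs(nxt, ext, path + [nxt])
        if dead_end:
            finalize(ref, path)

    dfs((node, ori), start_ref, [])
    assert best is not None
    return best


def _chain_seeds(seeds: Sequence[SeedHit]) -> list[SeedHit]:
    """Group collinear seeds (same node, strand and diagonal) and return
    the largest chain; ties go to the leftmost chain, then lowest node."""
    chains: dict[tuple, list[SeedHit]] = {}
    for s in seeds:
        diag = s.node_offset - s.read_offset if s.strand == "+" else s.node_offset + s.read_offset
        chains.setdefault((s.node, s.strand, diag), []).append(s)
    return max(
        chains.values(),
        key=lambda c: (len(c), -min(s.read_offset for s in c), -c[0].node),
    )


def extend_alignment(
    read: ReadRecord,
    seeds: Sequence[SeedHit],
    g: DeBruijnGraph,
    params: GraphAlignParams = GraphAlignParams(),
) -> AlignmentResult:
    """Align a seeded read to the graph and spell its corrected sequence.

    The largest collinear seed chain fixes an exactly-matching core; DFS
    with branch-and-bound extends the alignment across unitig boundaries
    on both sides.  If the search budget is exhausted the read is returned
    unchanged (conservative).
    """
    if not seeds:
        raise ValueError("extend_alignment requires at least one seed")
    chain = _chain_seeds(seeds)
    strand = chain[0].strand
    k = g.k

    seq, qual = read.seq, read.qual
    if strand == "-":
        L = len(seq)
        seq, qual = revcomp(seq), qual[::-1]
        chain = [
            SeedHit(L - k - s.read_offset, s.node, s.node_offset, "+") for s in chain
        ]
    chain.sort(key=lambda s: s.read_offset)
    node = chain[0].node
    rs, ns = chain[0].read_offset, chain[0].node_offset
    re_, ne = chain[-1].read_offset, chain[-1].node_offset

    node_seq = g.nodes[node].seq
    core_ref = node_seq[ns : ne + k]
    core_read = seq[rs : re_ + k]
    core_matches = sum(a == b for a, b in zip(core_read, core_ref))
    core_cols = len(core_ref)
    core_score = core_matches * params.match + (core_cols - core_matches) * params.mismatch

    budget = [params.max_branch]
    try:
        rscore, rref, rops, rmat, rcols, rover, rpath = _extend_side(
            g, node, "+", ne + k, seq[re_ + k :], params, budget
        )
        lquery = revcomp(seq[:rs])
        lscore, lref, lops, lmat, lcols, lover, lpath = _extend_side(
            g, node, "-", len(node_seq) - ns, lquery, params, budget
        )
    except _SearchAborted:
        return AlignmentResult(
            path=[],
            corrected_seq=read.seq,
            corrected_qual=read.qual,
            score=0.0,
            identity=0.0,
            status="unchanged",
        )

    # overhangs are read segments beyond the graph's reach: kept verbatim,
    # excluded from identity (they are unsupported, not matching)
    n_lover = len(lover)  # == number of leading read bases kept as-is
    corrected = seq[:n_lover] + revcomp(lref) + core_ref + rref + rover
    total_cols = lcols + core_cols + rcols
    total_matches = lmat + core_matches + rmat
    identity = total_matches / total_cols if total_cols else 0.0
    score = lscore + core_score + rscore

    # assemble qualities: kept bases retain their quality, inserted bases
    # get phred 2 ('#'), deleted read bases drop theirs
    aligned_lq = qual[n_lover:rs]
    left_quals = _ops_quals(aligned_lq[::-1], lops)[::-1]
    right_quals = _ops_quals(qual[re_ + k : len(seq) - len(rover)], rops)
    new_qual = (
        qual[:n_lover]
        + left_quals
        + qual[rs : re_ + k]
        + right_quals
        + qual[len(seq) - len(rover) :]
    )

    path = [(nid, _flip(o)) for nid, o in reversed(lpath)] + [(node, "+")] + rpath
    if strand == "-":
        corrected = revcomp(corrected)
        new_qual = new_qual[::-1]
        path = [(nid, _flip(o)) for nid, o in reversed(path)]

    return AlignmentResult(
        path=path,
        corrected_seq=corrected,
        corrected_qual=new_qual,
        score=score,
        identity=identity,
        status="corrected",
    )


def _flip(ori: str) -> str:
    return "-" if ori == "+" else "+"


def _ops_quals(read_qual: str, ops: Sequence[str]) -> str:
    out = []
    i = 0
    for op in ops:
        if op == "M":
            out.append(read_qual[i])
            i += 1
        elif op == "I":
            out.append("#")
        else:  # D: read base dropped
            i += 1
    return "".join(out)


def correct_cluster(
    reads: Sequence[ReadRecord],
    g: DeBruijnGraph,
    params: GraphAlignParams = GraphAlignParams(),
) -> dict[int, AlignmentResult]:
    """Align every cluster read to the cleaned graph.

    Reads without seeds get status 'unaligned'; reads whose best alignment
    identity falls below ``min_identity`` stay 'unchanged' (correction is
    conservative: a read we cannot place confidently is not touched).  No
    read is ever dropped.
    """
    results: dict[int, AlignmentResult] = {}
    for idx, read in enumerate(reads):
        seeds = find_seeds(read, g)
        if not seeds:
            results[idx] = AlignmentResult(
                path=[],
                corrected_seq=read.seq,
                corrected_qual=read.qual,
                score=0.0,
                identity=0.0,
                status="unaligned",
            )
            continue
        res = extend_alignment(read, seeds, g, params)
        if res.status == "corrected" and res.identity < params.min_identity:
            res = AlignmentResult(
                path=res.path,
                corrected_seq=read.seq,
                corrected_qual=read.qual,
                score=res.score,
                identity=res.identity,
                status="unchanged",
            )
        results[idx] = res
    return results
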