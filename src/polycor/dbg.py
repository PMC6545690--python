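"""Per-cluster de Bruijn graph: construction, unitig contraction, coverage
modeling and conservative tip/bubble removal.

The graph is double-stranded: a k-mer and its reverse complement are one
node (canonical representation), and every unitig carries its length in
k-mers and its average k-mer coverage.  Erroneous nodes are identified by
combining topology (tips = dead ends, bubbles = parallel branches) with a
coverage cutoff placed at the intersection of a two-Poisson mixture fit to
the node-coverage histogram by expectation-maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .kmers import canonical, revcomp
from .seqio import ReadRecord

__all__ = [
    "Unitig",
    "DeBruijnGraph",
    "CoverageModel",
    "CleanParams",
    "ModelError",
    "build_graph",
    "fit_coverage_model",
    "poisson_intersection",
    "detect_erroneous_nodes",
    "clean_graph",
    "write_gfa",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _count_with_flags(
    reads: Sequence[ReadRecord | str], k: int
) -> tuple[dict[str, int], dict[str, list[set[str]]]]:
    """Canonical k-mer counts plus observed extension flags.

    For every pair of consecutive ACGT-only windows in a read, the left
    node records the observed right-extension base and the right node the
    observed left-extension base, both expressed in the canonical
    orientation (the paper's 4+4 extension bits).  Arcs therefore reflect
    adjacencies actually seen in reads, never mere k-mer co-membership.
    """
    counts: dict[str, int] = {}
    flags: dict[str, list[set[str]]] = {}  # canon -> [left bases, right bases]

    def _flag(kmer: str) -> list[set[str]]:
        f = flags.get(kmer)
        if f is None:
            f = [set(), set()]
            flags[kmer] = f
        return f

    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        prev_w: Optional[str] = None
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                prev_w = None
                continue
            cw = canonical(w)
            counts[cw] = counts.get(cw, 0) + 1
            if prev_w is not None:
                x, y = prev_w, w
                cx, cy = canonical(x), cw
                if x == cx:
                    _flag(cx)[1].add(y[-1])
                else:
                    _flag(cx)[0].add(_COMP[y[-1]])
                if y == cy:
                    _flag(cy)[0].add(x[0])
                else:
                    _flag(cy)[1].add(_COMP[x[0]])
            prev_w = w
    return counts, flags


class ModelError(ValueError):
    """The coverage histogram does not support a two-component fit."""


@dataclass
class Unitig:
    """A contracted non-branching path: sequence, length in k-mers, and
    average k-mer coverage."""

    id: int
    seq: str
    length: int
    avg_cov: float


def _flip(ori: str) -> str:
    return "-" if ori == "+" else "+"


class DeBruijnGraph:
    """Contracted unitig graph over canonical k-mers.

    ``adj[(node_id, ori)]`` lists the oriented successors of a unitig read
    in orientation ``ori`` ('+' = stored sequence, '-' = reverse
    complement); successive unitigs overlap by exactly k-1 bases.  The
    underlying canonical k-mer counts are retained so the graph can be
    re-contracted after node removal.
    """

    def __init__(
        self,
        k: int,
        counts: dict[str, int],
        flags: dict[str, list[set[str]]],
    ):
        self.k = k
        self.counts = counts
        self.flags = flags
        self.nodes: dict[int, Unitig] = {}
        self.adj: dict[tuple[int, str], list[tuple[int, str]]] = {}
        self._kmer_index: dict[str, tuple[int, int, str]] = {}
        self._contract()

    # -- construction -------------------------------------------------

    def _ext(self, kmer: str, side: int) -> list[str]:
        """Observed extension bases of an oriented k-mer (side 0 = left,
        1 = right), restricted to extensions whose target still exists."""
        c = canonical(kmer)
        f = self.flags.get(c)
        if f is None:
            return []
        bases = f[side] if kmer == c else {_COMP[b] for b in f[1 - side]}
        out = []
        for b in sorted(bases):
            target = kmer[1:] + b if side == 1 else b + kmer[:-1]
            if canonical(target) in self.counts:
                out.append(b)
        return out

    def _succ(self, kmer: str) -> list[str]:
        return [kmer[1:] + b for b in self._ext(kmer, 1)]

    def _pred(self, kmer: str) -> list[str]:
        return [b + kmer[:-1] for b in self._ext(kmer, 0)]

    def _walk(self, start: str, in_path: set[str]) -> list[str]:
        """Extend right from an oriented k-mer along unambiguous arcs."""
        path = []
        cur = start
        while True:
            nxt = self._succ(cur)
            if len(nxt) != 1:
                break
            step = nxt[0]
            if len(self._pred(step)) != 1:
                break
            c = canonical(step)
            if c in in_path or step == revcomp(step):
                break  # circular path or unorientable palindrome
            path.append(step)
            in_path.add(c)
            cur = step
        return path

    def _contract(self) -> None:
        visited: set[str] = set()
        next_id = 0
        for km in sorted(self.counts):
            if km in visited:
                continue
            in_path = {km}
            right = self._walk(km, in_path)
            left = self._walk(revcomp(km), in_path)
            kmers = [revcomp(x) for x in reversed(left)] + [km] + right
            visited.update(canonical(x) for x in kmers)
            seq = kmers[0] + "".join(x[-1] for x in kmers[1:])
            if revcomp(seq) < seq:
                seq = revcomp(seq)
            total = sum(self.counts[canonical(x)] for x in kmers)
            self.nodes[next_id] = Unitig(
                id=next_id, seq=seq, length=len(kmers), avg_cov=total / len(kmers)
            )
            next_id += 1
        self._index()
        self._link()

    def _index(self) -> None:
        self._kmer_index.clear()
        k = self.k
        for nid, node in self.nodes.items():
            for off in range(node.length):
                w = node.seq[off : off + k]
                c = canonical(w)
                self._kmer_index[c] = (nid, off, "+" if w == c else "-")

    def _link(self) -> None:
        k = self.k
        self.adj = {}
        for nid, node in self.nodes.items():
            for ori in "+-":
                oseq = node.seq if ori == "+" else revcomp(node.seq)
                last = oseq[-k:]
                succs: list[tuple[int, str]] = []
                for y in self._succ(last):
                    hit = self._kmer_index.get(canonical(y))
                    if hit is None:
                        continue
                    mid, moff, _ = hit
                    mnode = self.nodes[mid]
                    if mnode.seq[moff : moff + k] == y and moff == 0:
                        succs.append((mid, "+"))
                    elif (
                        revcomp(mnode.seq[moff : moff + k]) == y
                        and moff == mnode.length - 1
                    ):
                        succs.append((mid, "-"))
                self.adj[(nid, ori)] = sorted(set(succs))

    # -- queries -------------------------------------------------------

    def oriented_seq(self, nid: int, ori: str) -> str:
        seq = self.nodes[nid].seq
        return seq if ori == "+" else revcomp(seq)

    def lookup_kmer(self, kmer: str) -> Optional[tuple[int, int, str]]:
        """(node id, offset in stored orientation, orientation of the
        canonical form) for a k-mer present in the graph."""
        return self._kmer_index.get(canonical(kmer))

    def total_kmer_mass(self) -> float:
        """Sum over nodes of length * avg_cov == total k-mer windows."""
        return sum(n.length * n.avg_cov for n in self.nodes.values())

    def remove_nodes(self, ids: Iterable[int]) -> "DeBruijnGraph":
        """Return a re-contracted graph with the given unitigs' k-mers
        removed."""
        drop: set[str] = set()
        k = self.k
        for nid in ids:
            seq = self.nodes[nid].seq
            for off in range(len(seq) - k + 1):
                drop.add(canonical(seq[off : off + k]))
        counts = {km: c for km, c in self.counts.items() if km not in drop}
        return DeBruijnGraph(k, counts, self.flags)

    def node_coverages(self) -> list[tuple[float, int]]:
        """(avg_cov, length) observations for coverage-model fitting."""
        return [(n.avg_cov, n.length) for n in self.nodes.values()]


def build_graph(reads: Sequence[ReadRecord | str], k: int) -> DeBruijnGraph:
    """Build the contracted, double-stranded de Bruijn graph of a cluster.

    Raises ValueError if k exceeds the shortest read.
    """
    if not reads:
        raise ValueError("no reads")
    min_len = min(len(r if isinstance(r, str) else r.seq) for r in reads)
    if k > min_len:
        raise ValueError(f"k={k} exceeds minimum read length {min_len}")
    counts, flags = _count_with_flags(reads, k)
    return DeBruijnGraph(k, counts, flags)


# -- coverage model ----------------------------------------------------


@dataclass
class CoverageModel:
    """Two-Poisson mixture over node average coverage.

    lambda_e / lambda_c are the means of the erroneous- and correct-node
    components, w_e / w_c their mixture weights, and ``cutoff`` the
    coverage below which a short tip or bubble branch is treated as
    erroneous.
    """

    lambda_e: float
    lambda_c: float
    w_e: float
    w_c: float
    cutoff: float
    log_likelihood: float = float("nan")
    n_iter: int = 0


def poisson_intersection(lambda_e: float, lambda_c: float, w_e: float, w_c: float) -> float:
    """Coverage cutoff at the crossing of the two weighted Poisson pmfs.

    Smallest x >= lambda_e where w_c * Pois(x; lambda_c) >= w_e *
    Pois(x; lambda_e); in closed form the crossing point is

        x* = (lambda_c - lambda_e + ln(w_e / w_c)) / ln(lambda_c / lambda_e)
    """
    if lambda_e >= lambda_c:
        raise ModelError("lambda_e must be smaller than lambda_c")
    x = (lambda_c - lambda_e + np.log(w_e / w_c)) / np.log(lambda_c / lambda_e)
    return float(max(x, lambda_e))


def _log_pois(x: np.ndarray, lam: float) -> np.ndarray:
    # continuous extension of the Poisson log-pmf (node coverages are means)
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def fit_coverage_model(
    node_covs: Sequence[tuple[float, float]],
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CoverageModel:
    """EM fit of a two-Poisson mixture to (avg_cov, weight) observations.

    Weights are typically node lengths, so a long unitig counts for the
    many k-mers it represents.  The log-likelihood is non-decreasing per
    iteration; iteration stops when its change drops below ``tol``.

    Raises
    ------
    ModelError
        Fewer than 10 observations, fewer than two distinct values, or a
        degenerate fit (lambda_e == lambda_c).
    """
    if len(node_covs) < 10:
        raise ModelError(f"need >= 10 observations, got {len(node_covs)}")
    x = np.asarray([c for c, _ in node_covs], dtype=float)
    w = np.asarray([wt for _, wt in node_covs], dtype=float)
    if np.unique(x).size < 2:
        raise ModelError("degenerate data: single distinct coverage value")

    mean = float(np.average(x, weights=w))
    lam_e = 1.0
    above = x[x > mean]
    lam_c = float(above.mean()) if above.size else mean * 2.0
    if lam_c <= lam_e:
        lam_c = lam_e * 2.0 + 1.0
    w_e = w_c = 0.5

    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_pe = np.log(w_e) + _log_pois(x, lam_e)
        log_pc = np.log(w_c) + _log_pois(x, lam_c)
        norm = np.logaddexp(log_pe, log_pc)
        ll = float(np.sum(w * norm))
        re = np.exp(log_pe - norm)
        rc = 1.0 - re
        se, sc = float(np.sum(w * re)), float(np.sum(w * rc))
        if se > 0:
            lam_e = max(float(np.sum(w * re * x) / se), 1e-9)
        if sc > 0:
            lam_c = max(float(np.sum(w * rc * x) / sc), 1e-9)
        w_e = se / (se + sc)
        w_c = 1.0 - w_e
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll

    if lam_e > lam_c:
        lam_e, lam_c = lam_c, lam_e
        w_e, w_c = w_c, w_e
    if abs(lam_c - lam_e) < 1e-6 or w_e < 1e-12 or w_c < 1e-12:
        raise ModelError("EM converged to a degenerate single-component fit")
    cutoff = poisson_intersection(lam_e, lam_c, w_e, w_c)
    return CoverageModel(
        lambda_e=lam_e,
        lambda_c=lam_c,
        w_e=w_e,
        w_c=w_c,
        cutoff=cutoff,
        log_likelihood=prev_ll,
        n_iter=n_iter,
    )


# -- cleaning ----------------------------------------------------------


@dataclass
class CleanParams:
    """Thresholds for erroneous-node removal.

    ``max_error_node_len`` defaults (in the pipeline) to avgReadLen - k:
    a single sequencing error corrupts at most that many k-mers, so true
    nodes longer than this are never removed.
    """

    max_error_node_len: int
    cutoff: float
    max_rounds: int = 10
    #: once tips/bubbles reach a fixpoint, also drop short low-coverage
    #: nodes regardless of topology (chimeric connections and tangled
    #: error paths are subsumed by the coverage cutoff); long nodes stay
    #: protected by max_error_node_len even at low coverage
    sweep_low_coverage: bool = True

    def __post_init__(self) -> None:
        if self.max_error_node_len < 1:
            raise ValueError("max_error_node_len must be >= 1")


def _detect_tips(g: DeBruijnGraph, p: CleanParams) -> set[int]:
    """Erroneous dead ends.

    A short, low-coverage node with arcs on at most one side is flagged
    when the junction it hangs from offers an alternative continuation of
    higher coverage (the signature of a sequencing-error branch).  A dead
    end that is the *only* continuation is a thin stretch of real
    sequence and is kept; fully isolated fragments are held to the
    stricter sweep threshold since there is no topology to consult.
    """
    if len(g.nodes) <= 1:
        return set()
    flagged = set()
    for nid, node in g.nodes.items():
        if node.length >= p.max_error_node_len or node.avg_cov >= p.cutoff:
            continue
        right = g.adj.get((nid, "+"), [])
        left = g.adj.get((nid, "-"), [])
        if not right or not left:
            flagged.add(nid)
    return flagged


def _bypass_exists(
    g: DeBruijnGraph,
    start: tuple[int, str],
    goal: tuple[int, str],
    avoid: int,
    max_kmers: int,
    min_cov: float,
) -> bool:
    """Bounded DFS: can ``goal`` be reached from ``start`` without passing
    through node ``avoid``, using only nodes with avg_cov > min_cov, in at
    most ``max_kmers`` k-mers of intermediate sequence?"""
    stack: list[tuple[tuple[int, str], int]] = [(start, 0)]
    seen: set[tuple[tuple[int, str], int]] = set()
    while stack:
        cur, used = stack.pop()
        for nxt in g.adj.get(cur, []):
            if nxt == goal:
                return True
            nid = nxt[0]
            if nid == avoid:
                continue
            node = g.nodes[nid]
            if node.avg_cov <= min_cov:
                continue
            nused = used + node.length
            if nused > max_kmers:
                continue
            key = (nxt, nused)
            if key in seen:
                continue
            seen.add(key)
            stack.append((nxt, nused))
    return False


def _detect_bubbles(g: DeBruijnGraph, p: CleanParams) -> set[int]:
    """Low-coverage branches of bubbles: a short, low-coverage node with a
    single predecessor and successor is flagged when a higher-coverage
    alternative path connects the same two anchors within a bounded
    detour.  The higher-coverage branch of a bubble is always kept."""
    flagged = set()
    for nid, node in g.nodes.items():
        if node.avg_cov >= p.cutoff or node.length >= p.max_error_node_len:
            continue
        right = g.adj.get((nid, "+"), [])
        left = g.adj.get((nid, "-"), [])
        if len(right) != 1 or len(left) != 1:
            continue
        succ = right[0]
        pred_rev = left[0]
        pred = (pred_rev[0], _flip(pred_rev[1]))  # oriented node preceding (nid, '+')
        if succ[0] == nid or pred[0] == nid:
            continue  # self-loop, not a simple bubble
        max_kmers = node.length + 2 * g.k
        if _bypass_exists(g, pred, succ, nid, max_kmers, node.avg_cov):
            flagged.add(nid)
    return flagged


def cap_cutoff(g: DeBruijnGraph, cutoff: float, max_error_node_len: int) -> float:
    """Bound a coverage cutoff by the graph's certainly-true nodes.

    A node longer than ``max_error_node_len`` cannot be erroneous (a
    single sequencing error corrupts fewer k-mers than that), so a cutoff
    above the coverage of such nodes contradicts the model that produced
    it; extraction concentrates coverage near the repetitive k-mer, which
    biases the fitted correct-component mean upward relative to the
    flanks.  The cutoff is clipped to 90% of the thinnest length-protected
    node's coverage.  A single read can spawn an error path of up to
    max_error_node_len + 1 k-mers, so only nodes comfortably beyond that
    count as certainly true here.
    """
    long_covs = [
        n.avg_cov for n in g.nodes.values() if n.length >= max_error_node_len + 2
    ]
    if not long_covs:
        return cutoff
    return min(cutoff, 0.9 * min(long_covs))


def detect_erroneous_nodes(g: DeBruijnGraph, p: CleanParams) -> set[int]:
    """Nodes flagged as erroneous on the current graph snapshot: tips
    (dead ends) and low-coverage bubble branches, both subject to the
    length and coverage thresholds."""
    return _detect_tips(g, p) | _detect_bubbles(g, p)


def clean_graph(g: DeBruijnGraph, p: CleanParams) -> DeBruijnGraph:
    """Conservative multi-round graph cleaning.

    The coverage threshold is ramped up over rounds toward the model
    cutoff: early rounds remove only the most obvious errors (coverage
    near 1), letting the true backbone contract into long unitigs that
    the ``max_error_node_len`` rule then protects permanently; later
    rounds apply the full cutoff to what is left.  Within a round, tip
    and bubble passes iterate to a fixpoint, then (with
    ``sweep_low_coverage``) short low-coverage nodes trapped in tangles
    -- neither dead ends nor bubble branches, e.g. chimeric connections
    -- are swept at the same threshold.  Nodes failing either the length
    or the coverage threshold are never removed, so an error-free graph
    passes through unchanged.
    """
    ramp = 1.5
    for _ in range(p.max_rounds):
        cut = min(p.cutoff, ramp)
        ramp *= 1.6
        pr = CleanParams(
            max_error_node_len=p.max_error_node_len,
            cutoff=cut,
            max_rounds=p.max_rounds,
            sweep_low_coverage=p.sweep_low_coverage,
        )
        round_changed = False
        while True:
            changed = False
            tips = _detect_tips(g, pr)
            if tips:
                g = g.remove_nodes(tips)
                changed = True
            bubbles = _detect_bubbles(g, pr)
            if bubbles:
                g = g.remove_nodes(bubbles)
                changed = True
            round_changed |= changed
            if not changed:
                break
        if p.sweep_low_coverage:
            junk = {
                nid
                for nid, n in g.nodes.items()
                if n.avg_cov < cut
                and n.length < p.max_error_node_len
                and g.adj.get((nid, "+"))
                and g.adj.get((nid, "-"))
                and not (
                    len(g.adj.get((nid, "+"), [])) == 1
                    and len(g.adj.get((nid, "-"), [])) == 1
                )
            }
            if junk:
                g = g.remove_nodes(junk)
                round_changed = True
        if cut >= p.cutoff and not round_changed:
            break
    return g


def write_gfa(g: DeBruijnGraph, path) -> None:
    """GFA1 export: segments with k-mer counts, links with k-1 overlaps."""
    k = g.k
    with open(path, "w") as h:
        h.write("H\tVN:Z:1.0\n")
        for nid in sorted(g.nodes):
            node = g.nodes[nid]
            h.write(
                f"S\t{nid}\t{node.seq}\tLN:i:{len(node.seq)}\t"
                f"KC:i:{round(node.length * node.avg_cov)}\tdp:f:{node.avg_cov:.3f}\n"
            )
        seen = set()
        for (nid, ori), succs in sorted(g.adj.items()):
            for mid, mori in succs:
                fwd = (nid, ori, mid, mori)
                rev = (mid, _flip(mori), nid, _flip(ori))
                if rev in seen:
                    continue
                seen.add(fwd)
                h.write(f"L\t{nid}\t{ori}\t{mid}\t{mori}\t{k - 1}M\n")
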