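"""Compact k-mer handling: 2-bit encoding, counting, repetitive-pattern
detection, read-pair extraction and the expected extracted-coverage formula.

Reads that overlap a short, highly repetitive pattern (canonically a
poly(A/T) homopolymer of 15 bp or longer) are the target of the whole
pipeline: this module decides which read pairs get extracted for
correction and provides the k-mer counting used by the clustering
prefilter and the de Bruijn graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import ReadPair, ReadRecord

__all__ = [
    "RepetitivePattern",
    "CoverageParams",
    "KmerCountTable",
    "encode_kmer",
    "decode_kmer",
    "revcomp",
    "canonical",
    "matches_pattern",
    "homopolymer_runs",
    "extract_pairs",
    "expected_kmer_coverage",
    "count_kmers",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEC = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

MAX_K = 31  # 2k bits must fit one 64-bit word


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_kmer(s: str) -> int:
    """Encode an ACGT string of length k <= 31 as a 2k-bit integer (A=00,
    C=01, G=10, T=11); lexicographic order of strings equals numeric order."""
    if not 1 <= len(s) <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {len(s)}")
    code = 0
    try:
        for base in s:
            code = (code << 2) | _ENC[base]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in k-mer") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a known k."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_DEC[(code >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class RepetitivePattern:
    """The repetitive motif that selects reads for correction.

    kind ``polyAT`` matches a run of >= k consecutive A's or T's, ``polyCG``
    the C/G analogue, ``explicit`` an exact k-mer (or its reverse
    complement).
    """

    kind: str = "polyAT"
    k: int = 15
    explicit_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("polyAT", "polyCG", "explicit"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("pattern k must be >= 1")
        if self.kind == "explicit":
            if self.explicit_seq is None or len(self.explicit_seq) != self.k:
                raise ValueError("explicit pattern requires explicit_seq of length k")

    @property
    def bases(self) -> str:
        """Bases whose runs constitute the pattern ('' for explicit)."""
        return {"polyAT": "AT", "polyCG": "CG", "explicit": ""}[self.kind]


def homopolymer_runs(seq: str, bases: str, min_len: int) -> list[tuple[int, int]]:
    """Half-open intervals of maximal single-base runs of length >= min_len
    restricted to the given bases."""
    if not bases:
        return []
    pattern = "|".join(f"{b}{{{min_len},}}" for b in bases)
    return [m.span() for m in re.finditer(pattern, seq)]


def matches_pattern(read: ReadRecord, pattern: RepetitivePattern) -> bool:
    """True iff the read contains the repetitive pattern.

    For homopolymer kinds this is a run of >= pattern.k consecutive
    identical bases ('or longer' semantics); reverse-complement symmetry is
    automatic because both bases of the complementary pair are scanned.
    """
    if pattern.kind == "explicit":
        seq = pattern.explicit_seq
        return seq in read.seq or revcomp(seq) in read.seq
    return bool(homopolymer_runs(read.seq, pattern.bases, pattern.k))


def extract_pairs(
    pairs: Sequence[ReadPair], pattern: RepetitivePattern
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Partition pairs into (selected, passthrough).

    A pair is selected when either mate matches the pattern; both lists
    preserve input order and together restore the input exactly.
    """
    selected: list[ReadPair] = []
    passthrough: list[ReadPair] = []
    for p in pairs:
        if matches_pattern(p.r1, pattern) or matches_pattern(p.r2, pattern):
            selected.append(p)
        else:
            passthrough.append(p)
    return selected, passthrough


@dataclass(frozen=True)
class CoverageParams:
    """Inputs of the expected extracted-coverage formula.

    C: mean per-base read coverage; l: read length; k: k-mer size;
    e: per-base error rate in [0, 1).
    """

    C: float
    l: int
    k: int
    e: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("coverage C must be positive")
        if not 1 <= self.k:
            raise ValueError("k must be >= 1")
        if self.k > self.l:
            raise ValueError(f"k={self.k} exceeds read length l={self.l}")
        if not 0 <= self.e < 1:
            raise ValueError("error rate e must be in [0, 1)")


def expected_kmer_coverage(p: CoverageParams) -> float:
    """Expected number of reads that fully and correctly cover a k-mer
    occurrence in the genome:

        C_k = ((l - k + 1) / l) * C * (1 - e)^k

    A read covers the k-mer only if it starts in one of the l-k+1 admissible
    positions, and all k bases over the k-mer must be error-free.  C_k is the
    expected number of read pairs per extracted cluster.
    """
    return (p.l - p.k + 1) / p.l * p.C * (1.0 - p.e) ** p.k


@dataclass
class KmerCountTable:
    """Map canonical (or as-seen) k-mer string -> occurrence count."""

    counts: dict[str, int]
    k: int
    canonical: bool = True

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(canonical(kmer) if self.canonical else kmer, default)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_kmers(
    reads: Iterable[ReadRecord | str], k: int, canonical_counts: bool = True
) -> KmerCountTable:
    """Count every ACGT-only k-mer window once; windows containing 'N' are
    skipped (they have no 2-bit code).  With canonical counting a k-mer and
    its reverse complement share one entry."""
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    counts: dict[str, int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            if canonical_counts:
                w = canonical(w)
            counts[w] = counts.get(w, 0) + 1
    return KmerCountTable(counts=counts, k=k, canonical=canonical_counts)
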