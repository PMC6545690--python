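"""Synthetic genomes and paired-end reads with per-base truth.

The generator emulates the data regime the corrector targets: a random
background genome with poly(A/T) homopolymer runs planted at well
separated loci, paired-end reads with Gaussian insert sizes, a baseline
substitution error rate genome-wide, and a strongly elevated error rate in
reads overlapping a planted run (quality 20 vs 31, roughly a tenfold
error-probability gap).  Inside the runs themselves errors are
homopolymer-length indels, the error mode homopolymers actually exhibit
on Illumina machines; elevated substitutions hit the rest of the hotspot
read.  Every read records its origin and the exact errors applied, so the
pipeline can be scored base-by-base against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kmers import revcomp
from .seqio import ReadPair, ReadRecord

__all__ = [
    "SimGenome",
    "MateTruth",
    "PairTruth",
    "SimReadSet",
    "simulate_genome",
    "simulate_reads",
    "apply_errors",
    "write_truth_table",
]

_BASES = np.array(list("ACGT"))

#: quality characters emulating the observed poly(A/T)-read quality gap
QUAL_NORMAL = chr(31 + 33)
QUAL_HOTSPOT = chr(20 + 33)


@dataclass(frozen=True)
class SimGenome:
    """Random genome with planted homopolymer loci (position, base, run length)."""

    sequence: str
    loci: tuple[tuple[int, str, int], ...]
    seed: int

    def run_intervals(self) -> list[tuple[int, int]]:
        return [(pos, pos + rl) for pos, _, rl in self.loci]


@dataclass(frozen=True)
class MateTruth:
    """Provenance of one read: oriented origin interval, strand, applied
    errors as (template_pos, kind, payload) with kind in {sub, ins, del}.

    Replaying ``ops`` on the oriented origin template reproduces the read
    exactly (see :func:`apply_errors`).
    """

    start: int
    end: int
    strand: str
    hotspot: bool
    ops: tuple[tuple[int, str, object], ...]


@dataclass(frozen=True)
class PairTruth:
    r1: MateTruth
    r2: MateTruth


def apply_errors(template: str, ops: Sequence[tuple[int, str, object]], read_len: int) -> str:
    """Replay recorded errors on an oriented origin template.

    Ops are addressed by template position; an 'ins' payload is inserted
    before that position, 'sub' replaces the base, 'del' skips ``payload``
    bases.  The result is truncated to ``read_len`` (sequencing cycles are
    fixed regardless of template slippage).
    """
    opmap = {pos: (kind, payload) for pos, kind, payload in ops}
    out: list[str] = []
    i = 0
    while i < len(template) and len(out) < read_len:
        hit = opmap.get(i)
        if hit is None:
            out.append(template[i])
            i += 1
        elif hit[0] == "sub":
            out.append(hit[1])
            i += 1
        elif hit[0] == "ins":
            out.append(hit[1])
            out.append(template[i])
            i += 1
        else:  # del
            i += int(hit[1])
    return "".join(out)[:read_len]


class SimReadSet:
    """Simulated paired reads plus complete per-read truth."""

    def __init__(
        self,
        genome: SimGenome,
        pairs: list[ReadPair],
        truth: list[PairTruth],
        read_len: int,
        params: dict,
    ):
        self.genome = genome
        self.pairs = pairs
        self.truth = truth
        self.read_len = read_len
        self.params = params

    def true_seq(self, ordinal: int, mate: int) -> str:
        """The error-free read: the first read_len bases of the oriented
        origin template."""
        mt = self.truth[ordinal].r1 if mate == 1 else self.truth[ordinal].r2
        tpl = self.genome.sequence[mt.start : mt.end]
        if mt.strand == "-":
            tpl = revcomp(tpl)
        return tpl[: self.read_len]

    def locus_of(self, ordinal: int, min_overlap: int = 15) -> Optional[int]:
        """Index of the planted locus one of the mates covers by at least
        ``min_overlap`` consecutive run bases, if any."""
        pt = self.truth[ordinal]
        for idx, (s, e) in enumerate(self.genome.run_intervals()):
            for mt in (pt.r1, pt.r2):
                gs, ge = _read_genome_interval(mt, self.read_len)
                if min(ge, e) - max(gs, s) >= min(min_overlap, e - s):
                    return idx
        return None

    def extractable_fraction(self, min_overlap: int = 15) -> float:
        n = sum(self.locus_of(i, min_overlap) is not None for i in range(len(self.pairs)))
        return n / len(self.pairs) if self.pairs else 0.0


def _read_genome_interval(mt: MateTruth, read_len: int) -> tuple[int, int]:
    """Genome interval covered by the read's read_len template bases."""
    if mt.strand == "+":
        return mt.start, min(mt.end, mt.start + read_len)
    return max(mt.start, mt.end - read_len), mt.end


def simulate_genome(
    length: int = 10_000,
    n_loci: int = 5,
    run_len_range: tuple[int, int] = (15, 25),
    seed: int = 0,
    *,
    read_len: int = 100,
    run_bases: str = "AT",
    max_background_run: int = 12,
) -> SimGenome:
    """Random genome with n_loci homopolymer runs at well-separated positions.

    The background is uniform over ACGT with homopolymer runs capped below
    the detection threshold, so every detectable run is a planted one.
    Deterministic per seed.
    """
    lo, hi = run_len_range
    if n_loci > 0 and length < n_loci * (hi + 2 * read_len):
        raise ValueError("genome too short to pack the requested loci")
    rng = np.random.default_rng(seed)

    seq = rng.choice(_BASES, size=length).tolist()
    run = 1
    for i in range(1, length):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_background_run:
            others = [b for b in "ACGT" if b != seq[i]]
            seq[i] = others[int(rng.integers(len(others)))]
            run = 1

    loci: list[tuple[int, str, int]] = []
    if n_loci:
        margin = read_len + 50
        spacing = (length - 2 * margin) // n_loci
        for i in range(n_loci):
            jitter = int(rng.integers(0, max(spacing // 4, 1)))
            pos = margin + i * spacing + jitter
            base = run_bases[int(rng.integers(len(run_bases)))]
            run_len = int(rng.integers(lo, hi + 1))
            seq[pos : pos + run_len] = base * run_len
            loci.append((pos, base, run_len))
    return SimGenome(sequence="".join(seq), loci=tuple(loci), seed=seed)


def simulate_reads(
    g: SimGenome,
    coverage: float = 30.0,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.001,
    hotspot_multiplier: float = 10.0,
    seed: int = 0,
    *,
    indel_prob: float = 0.3,
) -> SimReadSet:
    """Draw paired-end reads uniformly from the genome and plant errors.

    Pair count is round(C * G / (2l)).  The forward mate reads the
    fragment start, the reverse mate the reverse complement of the
    fragment end.  Reads overlapping a planted run ("hotspot" reads) take
    substitutions at rate ``error_rate * hotspot_multiplier`` outside the
    run and homopolymer-length indels (1-2 bases) inside it; all other
    reads take substitutions at ``error_rate``.
    """
    if read_len >= insert_mean:
        raise ValueError("read length must be below the mean insert size")
    if error_rate * hotspot_multiplier >= 0.5:
        raise ValueError("hotspot error rate must stay below 0.5")
    rng = np.random.default_rng(seed)
    genome = g.sequence
    G = len(genome)
    runs = g.run_intervals()
    n_pairs = int(round(coverage * G / (2 * read_len)))

    pairs: list[ReadPair] = []
    truth: list[PairTruth] = []
    pad = 6

    def make_mate(frag_start: int, frag_end: int, mate: int) -> tuple[ReadRecord, MateTruth]:
        if mate == 1:
            strand = "+"
            t_start = frag_start
            t_end = min(frag_start + read_len + pad, G)
        else:
            strand = "-"
            t_end = frag_end
            t_start = max(frag_end - read_len - pad, 0)
        template = genome[t_start:t_end]
        if strand == "-":
            template = revcomp(template)

        # genome interval of the read_len sequenced bases
        if strand == "+":
            gs, ge = t_start, t_start + read_len
        else:
            gs, ge = t_end - read_len, t_end
        overlaps = [
            (max(s, gs), min(e, ge)) for s, e in runs if min(e, ge) - max(s, gs) > 0
        ]
        hotspot = bool(overlaps)
        sub_rate = error_rate * hotspot_multiplier if hotspot else error_rate

        # template positions (oriented) lying inside a planted run
        run_tpos: set[int] = set()
        for s, e in overlaps:
            for gpos in range(s, e):
                tpos = gpos - t_start if strand == "+" else t_end - 1 - gpos
                if 0 <= tpos < read_len:
                    run_tpos.add(tpos)

        ops: list[tuple[int, str, object]] = []
        draws = rng.random(read_len)
        for tpos in range(min(read_len, len(template))):
            if tpos in run_tpos:
                continue
            if draws[tpos] < sub_rate:
                cur = template[tpos]
                alts = [b for b in "ACGT" if b != cur]
                ops.append((tpos, "sub", alts[int(rng.integers(3))]))

        if run_tpos and error_rate > 0 and rng.random() < indel_prob:
            tpos = sorted(run_tpos)[int(rng.integers(len(run_tpos)))]
            size = 1 + int(rng.random() < 0.25)
            if rng.random() < 0.5:
                ops.append((tpos, "ins", template[tpos] * size))
            elif len(template) >= read_len + size:
                ops.append((tpos, "del", size))

        ops.sort()
        seq = apply_errors(template, ops, read_len)
        qual = (QUAL_HOTSPOT if hotspot else QUAL_NORMAL) * len(seq)
        rec = ReadRecord(id="", seq=seq, qual=qual, mate=mate)
        return rec, MateTruth(
            start=t_start, end=t_end, strand=strand, hotspot=hotspot, ops=tuple(ops)
        )

    for ordinal in range(n_pairs):
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), read_len, G))
        start = int(rng.integers(0, G - insert + 1))
        r1, t1 = make_mate(start, start + insert, 1)
        r2, t2 = make_mate(start, start + insert, 2)
        r1 = ReadRecord(id=f"sim_{ordinal}/1", seq=r1.seq, qual=r1.qual, mate=1)
        r2 = ReadRecord(id=f"sim_{ordinal}/2", seq=r2.seq, qual=r2.qual, mate=2)
        pairs.append(ReadPair(ordinal=ordinal, r1=r1, r2=r2))
        truth.append(PairTruth(r1=t1, r2=t2))

    params = dict(
        coverage=coverage,
        read_len=read_len,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        error_rate=error_rate,
        hotspot_multiplier=hotspot_multiplier,
        indel_prob=indel_prob,
        seed=seed,
    )
    return SimReadSet(genome=g, pairs=pairs, truth=truth, read_len=read_len, params=params)


def write_truth_table(readset: SimReadSet, path) -> None:
    """Tab-separated truth dump: ordinal, mate, origin start/end, strand,
    hotspot flag, and the error list as pos:kind:payload triples."""
    with open(path, "w") as h:
        h.write("ordinal\tmate\tstart\tend\tstrand\thotspot\terrors\n")
        for ordinal, pt in enumerate(readset.truth):
            for mate, mt in ((1, pt.r1), (2, pt.r2)):
                errs = ";".join(f"{p}:{k}:{v}" for p, k, v in mt.ops)
                h.write(
                    f"{ordinal}\t{mate}\t{mt.start}\t{mt.end}\t{mt.strand}\t"
                    f"{int(mt.hotspot)}\t{errs}\n"
                )
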