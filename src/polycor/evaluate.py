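"""Correction-quality scoring against simulator truth, and summary
statistics over packaged NGA50 assembly-contiguity tables.

The gain metric is the standard error-correction scalar: with TP = errors
removed, FP = errors introduced and FN = errors remaining,

    gain = (TP - FP) / (TP + FN)

so gain = 1 means perfect correction and gain <= 0 means correction did
more harm than good.  Per-read error counts come from unit-cost edit
distance between each read and its true origin sequence.

The NGA50 tables shipped with the package record, for nine datasets
(six Illumina, three Illumina+PacBio hybrids), the contig and scaffold
NGA50 obtained by one assembler after each correction condition; the
functions here recompute the headline summary statistics (mean percent
NGA50 improvement over uncorrected data, per-condition best-case counts,
top-3 counts) from those grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import edlib
import pandas as pd

from .seqio import ReadPair
from .simulate import SimReadSet

__all__ = [
    "CorrectionStats",
    "NGA50Table",
    "TABLE2_CONDITIONS",
    "correction_stats",
    "load_packaged_table",
    "mean_improvement",
    "count_best",
    "top3_count",
]

#: correction conditions of the head-to-head comparison grid (the combined
#: two-tool row is evaluated separately and excluded from best-counting)
TABLE2_CONDITIONS = (
    "Uncorrected",
    "ACE",
    "BFC",
    "BLESS2",
    "BrownieCorrector",
    "Karect",
    "Reckoner",
)


@dataclass(frozen=True)
class CorrectionStats:
    """Error-correction confusion counts and the derived gain."""

    tp: int
    fp: int
    fn: int

    @property
    def gain(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            return 1.0 - self.fp
        return (self.tp - self.fp) / denom


def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def correction_stats(
    before: Sequence[ReadPair],
    after: Sequence[ReadPair],
    truth: SimReadSet,
    *,
    ordinals: Optional[Sequence[int]] = None,
) -> CorrectionStats:
    """Score corrected reads against their true origin sequences.

    For each read, errors are the edit distance to the error-free origin;
    per read, removed errors count toward TP, introduced errors toward FP,
    and whatever remains after correction toward FN.  ``ordinals``
    restricts scoring to a subset of pairs (e.g. only extracted ones).

    Raises
    ------
    ValueError
        If before/after ordinals do not line up.
    """
    by_after = {p.ordinal: p for p in after}
    tp = fp = fn = 0
    for p in before:
        if ordinals is not None and p.ordinal not in ordinals:
            continue
        q = by_after.get(p.ordinal)
        if q is None:
            raise ValueError(f"ordinal {p.ordinal} missing from corrected reads")
        for mate, rb, ra in ((1, p.r1, q.r1), (2, p.r2, q.r2)):
            true_seq = truth.true_seq(p.ordinal, mate)
            d_before = _edit_distance(rb.seq, true_seq)
            d_after = _edit_distance(ra.seq, true_seq)
            tp += max(d_before - d_after, 0)
            fp += max(d_after - d_before, 0)
            fn += d_before - max(d_before - d_after, 0)
    return CorrectionStats(tp=tp, fp=fp, fn=fn)


# -- NGA50 tables ------------------------------------------------------


@dataclass
class NGA50Table:
    """One NGA50 grid (a single contig or scaffold panel): rows are
    correction conditions, columns datasets D1..D9."""

    data: pd.DataFrame
    panel: str = "contig"

    @classmethod
    def from_tsv(cls, path, panel: str = "contig") -> "NGA50Table":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if (df <= 0).any().any():
            raise ValueError("NGA50 values must be positive")
        if "Uncorrected" not in df.index:
            raise ValueError("table must contain an 'Uncorrected' row")
        return cls(data=df, panel=panel)

    def conditions(self) -> list[str]:
        return list(self.data.index)


def load_packaged_table(panel: str) -> NGA50Table:
    """The packaged contig or scaffold NGA50 grid."""
    if panel not in ("contig", "scaffold"):
        raise ValueError("panel must be 'contig' or 'scaffold'")
    ref = resources.files("polycor.data").joinpath(f"nga50_{panel}.tsv")
    with resources.as_file(ref) as path:
        return NGA50Table.from_tsv(path, panel=panel)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mean_improvement(t: NGA50Table, tool: str) -> int:
    """Mean percent NGA50 change of ``tool`` over uncorrected data,
    averaged arithmetically over datasets and rounded half away from zero.
    """
    if tool not in t.data.index:
        raise KeyError(f"condition {tool!r} not in table")
    unc = t.data.loc["Uncorrected"]
    if (unc == 0).any():
        raise ZeroDivisionError("uncorrected NGA50 of zero")
    pct = 100.0 * (t.data.loc[tool] - unc) / unc
    return _round_half_away(float(pct.mean()))


def count_best(
    t: NGA50Table, conditions: Optional[Sequence[str]] = None
) -> tuple[dict[str, int], list[str]]:
    """Per-condition count of datasets where it has the highest NGA50.

    Returns (counts, tied_datasets); on a tie every tied condition is
    credited and the dataset is flagged.
    """
    conds = list(conditions) if conditions is not None else t.conditions()
    sub = t.data.loc[conds]
    counts = {c: 0 for c in conds}
    ties: list[str] = []
    for col in sub.columns:
        best = sub[col].max()
        winners = [c for c in conds if sub.at[c, col] == best]
        for w in winners:
            counts[w] += 1
        if len(winners) > 1:
            ties.append(col)
    return counts, ties


def top3_count(
    t: NGA50Table, condition: str, conditions: Optional[Sequence[str]] = None
) -> int:
    """Number of datasets where ``condition`` ranks among the top 3 values."""
    conds = list(conditions) if conditions is not None else t.conditions()
    sub = t.data.loc[conds]
    n = 0
    for col in sub.columns:
        third = sub[col].nlargest(3).min()
        if sub.at[condition, col] >= third:
            n += 1
    return n
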