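"""End-to-end demo: simulate a genome with poly(A/T) hotspots, correct the
reads that overlap them, and score the result against the known truth.

Run:  python examples/run_correction.py
"""

from polycor import (
    PipelineConfig,
    RepetitivePattern,
    correct_pairs,
    correction_stats,
    extract_pairs,
    simulate_genome,
    simulate_reads,
)

# A 10 kb genome with five planted homopolymer loci; 30x paired-end
# coverage; reads overlapping a run carry a tenfold error rate (the
# quality-20-vs-31 regime observed in real poly(A/T) reads).
genome = simulate_genome(length=10_000, n_loci=5, seed=1)
reads = simulate_reads(genome, coverage=30, read_len=100, seed=1)
print(f"simulated {len(reads.pairs)} pairs over {len(genome.loci)} homopolymer loci")

corrected, report, _ = correct_pairs(PipelineConfig(seed=1), reads.pairs)
print(
    f"extracted {report.extracted_pairs} pairs "
    f"({100 * report.extracted_pairs / report.total_pairs:.1f}%), "
    f"{report.n_clusters} clusters of sizes {report.cluster_sizes}"
)
print(
    f"modified {report.modified_pairs} pairs "
    f"({100 * report.fraction_modified:.1f}% of the dataset)"
)

# Gain on the extracted reads: fraction of their errors removed, minus
# errors introduced.  Gain 1 would be perfect correction; > 0.5 means most
# errors in the targeted reads are gone without collateral damage.
selected, _ = extract_pairs(reads.pairs, RepetitivePattern())
stats = correction_stats(
    reads.pairs, corrected, reads, ordinals={p.ordinal for p in selected}
)
print(
    f"errors removed {stats.tp}, introduced {stats.fp}, remaining {stats.fn}"
    f" -> gain {stats.gain:.3f}"
)
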