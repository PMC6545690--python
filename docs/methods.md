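# Methods

`polycor` is a targeted corrector: it assumes that a short-read dataset
is, for assembly purposes, already well handled everywhere *except* in
reads overlapping short, highly repetitive low-complexity patterns, and
that those reads carry an elevated error rate. Correction is therefore
restricted to the extracted subset; the contract for everything else is
byte-identity.

## Extraction

A pair is extracted when either mate contains the pattern. For the
homopolymer kinds (`polyAT`, `polyCG`) the test is a literal run of at
least k identical bases of the complementary pair, scanned by run length
("15-mer or longer" semantics); reverse-complement symmetry is automatic
because both bases are scanned. `N` bases never match a pattern and
score as mismatches in all alignments.

The expected number of extracted pairs per genomic pattern occurrence is

    C_k = ((l − k + 1)/l) · C · (1 − e)^k

(coverage C, read length l, per-base error rate e): a read must start in
one of the l − k + 1 admissible offsets and read the k pattern bases
without error. C_k is the expected cluster size and the coverage scale of
"non-repeated" k-mers among the extracted reads.

## Pair similarity and clustering

The similarity between two extracted pairs combines the overlap
alignment score of the pattern-carrying reads *and* of their mates; the
mates are what distinguish loci that share nothing but the homopolymer.
The overlap alignment score is the maximum of the best
suffix-of-one/prefix-of-the-other global alignment in either direction
and the empty overlap, so leading and trailing gaps are free while gaps
inside the overlap are penalized. Scoring defaults are match +1,
mismatch −1, gap −3 (linear), and an edge is created when the combined
score reaches τ = 0.4·l (40 for 100 bp reads) — roughly a confident
40 bp overlap. Because the pair orientation and mate order of two
fragments are arbitrary, the score is maximized over both mate matchings
and over reverse-complementing one pair as a unit.

All-vs-all alignment is avoided by a prefilter: only pairs sharing at
least one k-mer with count ≤ β·C_k (β = 2) that does not overlap the
homopolymer run are candidates. When C_k is not supplied it is estimated
as the 75th percentile of non-run k-mer counts among the extracted reads,
which tracks the near-run extracted coverage; a formula-based override is
available when C, l and e are known.

Louvain community detection (networkx implementation, seeded) is run
n_runs = 20 times; two pairs belong to the same stable core iff they
were co-clustered in at least θ·n_runs runs (θ = 0.8), and cores are the
connected components of that relation. A node consistently placed in a
singleton community is a singleton core; nodes with no stable
affiliation are unassigned. Cores smaller than min_cluster_size = 5
pairs, and all unassigned pairs, pass through uncorrected — too few
reads cannot support a de Bruijn graph consensus.

## Per-cluster de Bruijn graph

The graph is double-stranded: a k-mer and its reverse complement are one
node, keyed by the lexicographically smaller form, with k ≤ 31 so a
k-mer fits a 64-bit word at 2 bits per base. Arcs are recorded from
adjacencies actually observed in reads (4 left + 4 right extension
bits per k-mer), never inferred from mere co-membership of the k-mer
set — membership-only arcs invent hairpin connections whenever a k-mer
happens to neighbor its own reverse complement. Non-branching paths are
contracted into unitigs carrying their length (in k-mers) and average
k-mer coverage; total k-mer mass is conserved by construction.

A homopolymer run of length ≥ k + 1 collapses into a single node with a
self-arc. This is the central structural limitation: the graph
represents *that* the run exists but not *how long* it is (see
Limitations).

### Coverage model

The node-coverage histogram of a cluster graph is bimodal: erroneous
nodes near coverage 1, correct nodes near C_k. A two-component Poisson
mixture is fit by EM on (avg_cov, weight) observations, weighted by node
length by default so a long unitig counts for the many k-mers it
represents. The Poisson pmf is evaluated through its continuous
(gamma-function) extension because node averages are not integers.
Initialization: λe = 1, λc = mean of observations above the overall
mean, weights ½/½; iteration stops when the log-likelihood changes by
less than 1e-6 (at most 500 iterations; the log-likelihood is
non-decreasing, which the tests assert). Degenerate inputs — fewer than
10 observations, a single distinct value, or a collapsed fit — raise a
model error, and the pipeline then falls back to
cutoff = max(2, mean coverage / 4), which for a clean (error-free)
cluster removes nothing.

The cutoff sits at the smallest x ≥ λe where the correct component's
weighted pmf overtakes the erroneous one's; in closed form the crossing
is x* = (λc − λe + ln(we/wc)) / ln(λc/λe).

Extraction concentrates coverage near the run (every extracted pair
covers it) and the flanks thin out with distance, so a single Poisson
overstates the correct component's mean and the crossing can land above
genuine flank coverage. The pipeline therefore caps the cutoff at 90% of
the coverage of the thinnest *certainly-true* node — one longer than
maxErrorNodeLen + 1 k-mers, beyond what a single read's errors can spawn.

### Cleaning

A tip (dead end) or bubble branch is erroneous when it is shorter than
maxErrorNodeLen = avgReadLen − k k-mers *and* below the coverage cutoff;
nodes failing either test are never removed, so an error-free graph is a
fixpoint. Bubble branches are found by bounded path search: a
single-in/single-out low-coverage node is a branch when its anchors
reconnect through strictly higher-coverage nodes within a bounded detour
(its own length + 2k k-mers). This subsumes the textbook two-branch
bubble and also catches branches whose "sibling" is a segment inside a
longer unitig.

Cleaning is multi-round and conservative in a specific sense: the
coverage threshold is ramped (1.5, ×1.6 per round) up to the model
cutoff. Early rounds remove only near-singleton junk; the backbone then
contracts into long unitigs that the length rule protects permanently,
and only then does the full cutoff apply to the remainder. Within a
round, tip and bubble passes iterate to a fixpoint, after which short
low-coverage nodes trapped in tangles (connected on both sides but
branching — chimeric connections and interlocking error paths that are
neither dead ends nor simple bubbles) are swept at the same threshold.
Ten rounds by default; the graph is re-contracted from the surviving
k-mer set after every removal.

## Read-to-graph alignment

Each read's k-mers that occur exactly once in the graph (counting both
strands; self-reverse-complement k-mers are ambiguous and skipped)
become seeds. Collinear seeds — same node, strand and diagonal — are
chained; the largest chain wins, ties to the leftmost. The chained core
maps exactly onto one unitig and is replaced by the unitig's bases;
both flanks are then extended by depth-first search over the graph,
scoring candidate path sequences against the read flank by global
alignment with a free path end. Branch-and-bound prunes any partial path
whose optimistic completion (best DP cell plus perfect matches for the
unconsumed read suffix) cannot beat the current best, and the search
aborts — leaving the read unchanged — after max_branch = 1000 node
visits. A self-arc is re-entered only while the read is still reading
the run it spells; past that point it is a dead end.

Where a path dead-ends before the read does, the unaligned read overhang
is kept verbatim (original bases and qualities) and excluded from
identity — the graph has no opinion about it, and aligning it as
deletions would silently truncate reads. A read is accepted as corrected
when the identity over aligned columns reaches min_identity = 0.8;
otherwise it passes through unchanged. Corrected substitutions keep the
original base quality, bases inserted by correction get quality '#'
(phred 2), and deleted bases drop theirs; read length may change when
indels are corrected. Correction is idempotent, and every corrected
sequence is spelled by a real path in the cleaned graph (asserted by
re-walking the path in the tests).

## Synthetic data

The generator emulates the regime the corrector targets, not Illumina in
general. A uniform-random genome (background homopolymer runs capped at
12 bp so every detectable run is planted) carries n_loci well-separated
poly(A/T) runs of 15–25 bp. Pairs are drawn uniformly with Gaussian
insert sizes; count = round(C·G/(2l)). Reads overlapping a planted run
("hotspot" reads) take substitutions at rate e·m *outside* the run and,
with probability 0.3, one homopolymer-length indel (1–2 bases) *inside*
it; all other reads take substitutions at rate e. Defaults e = 0.001 and
m = 10 reproduce the observed quality split: hotspot reads at ~1% error
(phred 20) vs ~0.1% (phred 31) elsewhere; quality strings are constant
at those two values and are annotation only — the corrector never reads
them. Every read records its origin interval, strand and exact error
ops, and replaying the ops reproduces the read byte-for-byte (asserted
in tests).

What the generator does not emulate: position-dependent error profiles
along the read cycle, GC bias in coverage, adapter or quality artifacts,
and repeats other than the planted homopolymers. Passing the benchmark
therefore demonstrates the pipeline's behavior under idealized
uniform-coverage, well-separated-locus conditions, not performance on
real libraries.

## The default benchmark

10 kb genome, 5 loci, 30× coverage, 100 bp reads, insert 300 ± 30,
e = 0.001, m = 10. About 9% of pairs are extracted (matching the
simulator's ground truth within a few percent), clusters recover loci
with homogeneity 1.0, and the correction gain on extracted reads is
0.51–0.58 across seeds with zero introduced errors. These sizes keep a
full pipeline run under a minute on one core; the acceptance script runs
the benchmark twice (once for the determinism check).

## Known limitations

* **Homopolymer length is unrecoverable when the run exceeds k.** The
  run collapses to a self-loop node, so the alignment spells each read's
  own run length and length-changing indels inside long runs are neither
  fixed nor worsened. This is the dominant residual error class on the
  benchmark (the gain ceiling), and it is shared by any k-mer-graph
  corrector with k below the run length. Runs of exactly k are fully
  determined and such indels are corrected.
* Clusters need roughly C_k ≥ 10 pairs for a reliable consensus; below
  min_cluster_size the reads pass through. Large insert-size variance
  spreads the mates and weakens both the prefilter and the mate-overlap
  signal, fragmenting clusters.
* One pattern per invocation; multiple patterns are separate runs.
* The bounded bubble search can miss parallel error paths longer than
  the detour bound; the coverage sweep catches most but not all, so very
  high error rates leave residual junk nodes that cost search budget.
* Clusters are corrected independently and merged by ordinal, so results
  are scheduling-independent; the current implementation runs them
  sequentially (the `threads` knob is a forward-compatible no-op).
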