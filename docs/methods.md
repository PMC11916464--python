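# Methods

## Problem setting and model

Linked-read sequencing tags short reads with fragment barcodes: every
read cloud (group of same-barcode reads) derives from one long DNA
fragment, up to barcode reuse across distant fragments. Within a target
window this package reconstructs the fragments ("molecules"), phases
them into the two parental haplotypes using heterozygous SNPs, assembles
each haplotype's reads separately, and reads variants off the assembled
contigs. The library is characterized by four statistics: raw short-read
coverage *C*, physical fragment coverage *C_F*, within-fragment read
coverage *C_R* (so *C* ≈ *C_F · C_R*), and mean fragment length μ_FL.

All internal coordinates are 0-based half-open; 1-based conventions
appear only at the VCF/PAF file boundary.

## Barcode deconvolution and molecule annotation

Reads sharing a barcode are sorted by position and split wherever the
gap between successive reads exceeds a boundary threshold — 50 kb for
10x-style libraries, 20 kb for stLFR, reflecting the different fragment
length scales; both are configurable. This is exactly 1-D single-linkage
clustering at the threshold, and the unit tests verify equivalence to a
brute-force oracle. Groups with fewer than `min_reads` (default 2) reads
are discarded: a singleton carries no linkage information, though
`min_reads=1` is permitted.

Each molecule is annotated at every het SNP covered by its reads: bases
with quality ≥ 13 vote, the majority base maps to code 0 (reference) or
1 (alternate), and loci with a tie or a majority third allele are left
unannotated. Annotation is order-independent by construction.

## Haplotype partitioning

The two parental haplotypes carry complementary alleles at every het
SNP, so molecule annotation vectors fall into two orientation classes.
Phase blocks are the connected components of the molecule–locus sharing
graph; no attempt is made to bridge blocks with SNP-free barcode
linkage. Within a block the partition is found by deterministic
agglomerative clustering:

* every molecule starts as a cluster with an orientation bit;
* the score of a cluster pair is max over relative orientation of
  (#agreements − #disagreements) between consensus vectors on shared
  loci — equivalently |⟨s_A, s_B⟩| on sign vectors in {−1, 0, +1},
  which makes the whole procedure a sequence of integer matrix/vector
  products;
* the highest-scoring pair with score > 0 is merged (orientations
  flipped as needed) until no positive pair remains.

Molecules in clusters that never attach to the main cluster (equal
evidence for both orientations) remain unphased and are excluded from
assembly rather than guessed. Determinism: molecules are canonically
ordered by (leftmost annotated locus, barcode, start) and the first
maximal score-matrix entry in that order is merged; this realizes the
"smallest leftmost-locus/barcode pair" tie-break in a vectorizable form.
HP1/HP2 labels are arbitrary per block and are canonicalized so that
HP1 carries allele 0 at the block's leftmost phased locus. Exhaustive
2-coloring search reproduces the partition on small instances, and on
simulated molecules (200 molecules, 20 SNPs) assignment accuracy is
100% at allele error 0 and ≥ 95% at error 0.02.

## Local assembly

Per phase block, the reads of HP1 and HP2 molecules are assembled
independently. The external adapter writes a FASTQ pair and invokes a
configurable command template (default SPAdes; the exact assembler
arguments are exposed raw because different assemblers want different
flags). The builtin assembler is a plain de Bruijn graph: k-mers
(default k = 31, odd, < read length) from both strands of every read;
unitigs by non-branching path compression; dead-end tips shorter than
2k removed once and the graph recompressed; contigs ≥ 2k emitted in
canonical form (lexicographically smaller of contig/reverse complement),
ordered by length then sequence, which makes output invariant to input
strand and order. The k-mer machinery is integer-packed and vectorized
(sorted unique array + binary search for edges), so a 50 kb window
assembles in about a second. The builtin assembler does no error
correction, bubble popping or scaffolding — it is intended for
low-error, high-coverage read sets such as the phased reads of one
window; noisy real libraries should use the external mode.

## Contig-to-reference comparison and calling

External mode uses minimap2 (`-x asm5 --cs -c`); the PAF cs difference
strings are parsed into match/mismatch/insertion/deletion operations.
The builtin aligner is an anchor-chaining aligner: k-mers (k = 21)
unique in both contig and window become anchors, maximal same-diagonal
anchor runs are chained by a colinear DP (small gap penalty, head
overlaps at gap junctions trimmed), outer anchors are extended by direct
base comparison, and each short unanchored segment between chained runs
is resolved by common prefix/suffix trimming into a mismatch run, a
single clean gap, or a deletion-plus-insertion block. A unit-cost
edit-distance alignment was deliberately rejected here: on random
sequence it shreds a large gap into dozens of runs separated by chance
matches, destroying SV size fidelity, whereas anchor chaining recovers
each indel as one contiguous operation. Both contig strands are tried;
the more-anchored one wins.

Variant extraction walks the operations: mismatches become SNPs, gap
operations become VCF-style anchored indels (one leading reference
base), which are then left-aligned against the reference. Alignments
with mapq < 5 or reference span < 10 kb are ignored (short, dubious
placements breed artifact calls; both thresholds are configurable and
scaled to ~50 kb windows).

Overlapping contigs within one haplotype produce redundant calls, which
a chaining step collapses: any same-type pair within 500 bp whose size
similarity (min/max) and sequence similarity (normalized edit similarity
for insertions/SNPs, reciprocal span overlap for deletions) reach 0.7 is
merged transitively (union–find); the representative is the call from
the longest supporting contig, ties broken leftmost then largest. The
0.7 threshold is intentionally stricter than the 0.1 used for
benchmarking: chaining is intra-caller deduplication, not tolerant
matching. The two haplotype sets are then merged with the same
comparator under greedy nearest-first one-to-one matching: shared
variants become `1|1`, haplotype-private ones `1|0` or `0|1`, each
carrying the phase-block id as the VCF `PS` value. Contig-derived SNPs
present in the input small-variant VCF keep their contig phase;
contig-only SNPs are retained but flagged `CONTIG_ONLY` rather than
deleted, because alignment-based small-variant callers are near-perfect
for SNPs and a contig-only SNP is more often an assembly or alignment
artifact. Regions with no phase block yield an empty VCF and an
`UNPHASED` diagnostic; an optional joint-unphased mode instead
assembles all reads together and emits homozygous calls (off by
default).

SVs are indels ≥ 50 bp, binned as [50 bp, 1 kb), [1 kb, 10 kb), ≥ 10 kb.

## Benchmarking

The evaluator mirrors the standard SV benchmarking predicate: same type,
start distance ≤ r (default 200 bp), size similarity ≥ P (0.1), sequence
similarity ≥ p (0.1, insertions only — a deletion's sequence is the
reference span, so size similarity stands in), reciprocal overlap ≥ O
(0), with greedy nearest-first one-to-one matching. Matched truth
entries are TP (TP_GT when genotypes agree phase-agnostically: `1|0`
equals `0|1` because per-block phase labels are arbitrary), unmatched
truth are FN, unmatched calls FP; recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 their harmonic mean,
GT_accuracy = TP_GT/TP. Greedy matching can in principle differ from
optimal bipartite matching; tests compare against an optimal-matching
oracle on randomized instances.

## Simulator

`simulate_diploid` builds a uniform-random reference window, drops het
SNPs at a per-bp rate (default 10⁻³, human-like heterozygosity) with the
alternate allele assigned to haplotype 1 or 2 by fair coin, and applies
non-overlapping SVs per genotype (het carrier also by coin). SNPs are
kept out of SV footprints so truth annotation stays unambiguous.
`simulate_molecules` draws fragments per haplotype to physical coverage
C_F/2 each, lengths exponential with mean μ_FL truncated to
[1 kb, 5 μ_FL], uniform starts, barcodes uniform over a 500 000-barcode
pool (collisions intended — they are what deconvolution must resolve).
`simulate_linked_reads` emits per-fragment read pairs at coverage C_R
(pair count Poisson with mean C_R·len/(2·read_len); insert
Normal(350, 50); iid base errors, default 0) and writes them **at their
true reference placement** — no read mapper is in the loop, so pipeline
tests isolate the calling algorithms from mapping artifacts. Reads
spanning a deletion get a D CIGAR operation; reads overhanging novel
inserted sequence are clipped; read pairs entirely inside an insertion
are absent from the BAM by default, deliberately reproducing the main
real-data failure mode of large-insertion calling (novel-sequence reads
do not map and never reach a region-based caller). A
`retain_insertion_reads` flag anchors them soft-clipped at the insertion
point instead, for experiments that need the novel sequence present.
Fixed seeds give byte-identical outputs, and truth logs (read →
molecule → haplotype) are complete.

What the simulator does **not** emulate: GC and coverage bias, chimeric
fragments, duplicate reads, barcode sequencing errors, mapping errors
and reference bias (placements are truth), and repeat structure
(windows are uniform-random sequence, so assembly and anchoring face no
segmental duplications). Passing simulation suites therefore validates
the algorithmic chain under clean conditions; they do not predict
real-library accuracy, which is dominated by exactly those effects.

## Validation study sizes and numerical choices

The end-to-end deletion study uses twenty independent 50 kb regions
(10x preset, error-free, builtin assembler and aligner), deletion sizes
geometric between 100 bp and 2 kb, genotypes alternating het/hom; it is
scored at r=200/P=0.1/p=0.1/O=0 and completes in a couple of minutes on
one CPU. Oracle-equivalence suites run 100 randomized instances each for
deconvolution (500 reads, 20 barcodes) and chaining (50 variants).
Degenerate inputs are defined everywhere: empty read sets assemble to
nothing, unphaseable regions produce empty VCFs with a diagnostic flag,
zero-denominator metrics are 0 by convention, and batch mode isolates
per-region failures. All randomness flows through seeded numpy
generators; repeated runs are byte-identical.

## Known limitations

* Insertions longer than the read length cannot be fully reconstructed
  from mapped reads alone; they surface as FN (by design, matching the
  input-data limitation).
* The builtin aligner reports gap placements up to junction ambiguity
  (a few bases when gap-flank bases coincide); after left-alignment
  this is immaterial at benchmarking tolerances but positions may
  differ by 1–5 bp from an affine-gap aligner's.
* Unphased molecules are never used for assembly; regions whose
  molecules mostly miss het SNPs lose coverage and may under-call.
* One alignment per contig: duplications/inversions and split
  placements are out of scope (deletion/insertion calling only).
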