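# Methods

This note documents the models, parameters and numerical choices behind
`tsoumi`, and what the synthetic-data results do and do not demonstrate.

## Read model and motif grammars

A 5′ UMI read begins with the TSO footprint
`adapter-suffix + UMI(8 nt) + spacer + GG`, where the adapter is the
23-nt ISPCR sequence `AAGCAGTGGTATCAACGCAGAGT` and the default spacer is
`CTAAC`. Two grammar dialects are compiled:

- `spacer`: read-1 adapter suffixes of length 2..23 are accepted,
  followed by 8 any-bases, the spacer, and the `GG` anchor.
- `nospacer`: suffixes of length 4..23, no spacer.

The read-2 rescue grammar accepts only the short remnants a Tn5 cut inside
the TSO leaves behind (`GAGT`, `AGT`, `GT` by default), then the same
UMI/spacer/anchor tail. Matching is exact (no mismatches inside the
adapter, spacer or anchor) and longest-suffix-first, so the reported suffix
length is maximal. Read 1 takes precedence when both mates match: read 1
is the designed configuration, read 2 the rescue. The anchor is `GG`, not
`GGG`: the third riboguanosine is templated and stays on the read, so the
trimmed read begins with one G followed by cDNA; the simulator's alignment
records therefore describe the cDNA span only (the G is soft-clipped).
With this adapter no suffix of one length is a prefix of a longer suffix
followed by a consistent spacer/anchor, so the longest-first search cannot
misreport the truncation point; a property test checks equivalence with a
brute-force enumeration of every admissible suffix length.

After extraction, pairs are cropped to 75 bp and pairs with either mate
≤ 25 bp are dropped (strictly greater than 25 survives).

## Strand-invasion detection

For every mapped UMI read the 20-nt window adjacent to the read start is
extracted strand-aware: `genome[start−20 .. start)` for + reads, reverse
complement of `genome[end .. end+20)` for − reads. Reads whose window runs
off the contig are dropped and counted. PCR duplicates are collapsed on
the key (UMI, chromosome, start, strand, window); strand is part of the
key because opposite-strand reads at one coordinate have different
adjacent sequences. The first-encountered record per key survives;
survivor identity never affects any statistic because only keys are
counted.

A match at mismatch level `m ∈ {0..3}` is an exact occurrence, anywhere in
the window, of the UMI's 3′ `(8−m)`-suffix followed by the motif string
(empty, `GGG`, or `spacer+GGG`). Only consecutive 5′ mismatches are
forgiven — internal mismatches never are. "Anywhere in the window" is the
default because an adjacency-only variant would make the window size
meaningless; `adjacent_only=True` is available for sensitivity analysis.
The report tabulates cumulative match counts per level × motif mode next
to the analytic random-match expectation
`1 − (1 − 4^−L)^(20 − L + 1)`, `L = (8−m) + len(motif)`, valid under an
i.i.d. uniform-base null (our simulated genomes are uniform; real genomes
are not, so on real data the null is a lower bound). The invasion filter
discards reads matching at `m ≤ 1` with motif-free matching; motif-
conditioned filtering exists behind a flag but is off by default because
only the mismatch cap of the filter is well established.

The read-start profile tallies base composition at the 6 positions
immediately 5′ of the read start over up to 500,000 randomly selected
deduplicated reads (seeded, without replacement).

## Synthetic data generator

`SimConfig` defaults describe the demo conditions: 2 chromosomes ×
100 kb of uniform random sequence, 40 single-exon genes on random strands
(well separated so no read can reach two genes at the 25 % overlap
threshold), 8 cells × 2,000 molecules, read length 75, fragment length
150, 50 % UMI reads, 5 % genomic background, 2 % strand invasion, 5 %
intra-TSO tagmentation, 50 heterozygous SNPs, error-free bases. Error
rate, PCR duplicate factor, and adapter-truncation weights (uniform over
suffix lengths {2,3,4} for read-2 UMIs — the true distribution of Tn5 cut
positions inside the TSO is unknown, so this is a stand-in, not a claim)
are configurable. Per-gene expression is uniform by default; a Dirichlet
concentration knob (`gene_weight_alpha`) induces heterogeneous expression
for saturation/correlation demonstrations.

Invasion reads copy their UMI from the genome upstream of the read start.
Two layouts are generated: the plain layout copies the 8 nt immediately
upstream; with probability `p_invasion_ggg` (default 0.5) the
riboguanosine footprint is planted instead — `GGG` occupies the 3 nt
adjacent to the read start and the UMI is copied from the 8 nt immediately
5′ of it, mirroring the annealing geometry `UMI–spacer–rGrGrG` of the
oligo. Both layouts put the UMI inside the 20-nt detection window, so
rate-recovery statistics are layout-independent, while only the planted
layout produces G-enrichment adjacent to the read start and
motif-conditioned matches.

Planted heterozygous SNPs alternate alt/ref deterministically across a
carrier cell's covering reads, starting with alt, so the alt fraction is
~50 % and any site with coverage > 2 is guaranteed ≥ 2 alt reads. This
makes "100 % recovery of covered SNPs on error-free reads" a theorem of
the construction rather than a coin flip; real data would show binomial
allele sampling and allelic imbalance, which the benchmark inherits from
its inputs rather than from this generator. The exome truth VCF contains
the planted SNPs with passing hard-filter annotations plus decoy variants
that each fail exactly one filter and are planted in no read.

The simulator is its own aligner: it emits one alignment record per pair
(the trimmed, reoriented UMI-bearing mate, or mate 1 for non-UMI pairs)
at the true position, with the aligned bases stored so the pileup caller
can run without re-alignment. Consequences: mapping ambiguity, soft-clip
artifacts and alignment errors are outside what the tests can show;
passing tests demonstrate the statistics and filters are correct given
correct alignments, not that any aligner is.

Eight-nt UMIs collide at the birthday rate (≈ `C(M,2)/4^8` per gene-cell
with M molecules). Unique counting therefore recovers *distinguishable*
molecules; the tests assert exact agreement with the distinct planted UMIs
and bound the collision deficit rather than pretending collisions cannot
happen.

## Molecule counting and the edit-distance diagnostic

Gene assignment requires ≥ 25 % of the aligned length to overlap a gene's
exonic span; reads meeting the threshold in several genes are discarded as
ambiguous. UMI reads are assigned strand-aware, internal reads unstranded.
The directional collapse processes UMIs in descending count then
lexicographic order and links Hamming-distance-1 pairs when the larger
count is ≥ 2×(smaller) − 1; components count once. Components are found by
union-find, so the result is independent of processing order.

The edit-distance diagnostic takes the UMI multiset of
position-deduplicated reads per gene (or per gene and cell) — repeated
identical UMI sequences captured at different positions are kept, since
they are exactly what UMI inflation would produce. Pairwise Levenshtein
distances (edlib; Hamming available) are compared against draws of
matching set sizes from the pooled UMIs using a two-sided Mann–Whitney
test. Pairwise distances within a set are not independent, so with very
many pairs the p-value is anticonservative; the raw distance distributions
are always emitted so any alternative comparison can be applied.

## SNP benchmark

Exome variants must pass all of `QD > 2, FS < 60, SOR < 3, MQ > 40,
MQRankSum > −12.5, ReadPosRankSum > −8` (strict inequalities; a missing
annotation passes by default, configurable), be SNVs, and lie in the
capture intervals. Mitochondrial contigs are excluded by default.
Multi-allelic records are decomposed before comparison. Matching requires
the identical alt allele; position-only matching is available behind a
flag. The internal pileup caller (≥ 2 alt reads, alt fraction ≥ 0.2,
QUAL = Phred of a binomial test at 1 % base error, capped at 99) exists so
the benchmark runs end-to-end on synthetic data; VCFs from any external
caller are accepted as input. Depth curves downsample reads without
replacement (seeded) and rebuild the reference list at each depth; a
requested depth beyond the available reads is computed on the full data
and flagged. Cell aggregation merges the reads of k sampled cells before
calling, with the reference list built from pooled coverage.

## Detection, diversity, correlation

Gene detection uses strict thresholds (count > 0, count > 5). Gene
diversity resamples `n_cells` (default 10) cells per cell type
`n_iter` (default 100) times and counts genes expressed in strictly more
than `min_cells` (default 2) of the sampled cells; the boundary is
configurable because "more than two cells" and "two or more cells" both
appear in common usage. Diversity uses the summed UMI+internal matrix.
Cell–cell similarity is Kendall tau-b (scipy, tie-corrected); the default
restricts each pair to genes expressed in both cells (`shared="pair"`),
with `shared="all"` restricting to genes expressed in every compared cell.
An optional gene blacklist (e.g. mitochondrial/ribosomal genes) is applied
before all statistics.

## Problem sizes and determinism

The shipped analyses and acceptance computations use 50,000-read invasion
datasets, 100,000-pair extraction datasets, 20 error-model replicates of
800 reads, and 4-cell SNP benchmarks of 5,000 reads per cell — sizes at
which every binomial tolerance in the tests is meaningfully tight while a
full run stays in the minutes range on one core. Every random choice
(simulation, downsampling, resampling, profile subsampling) flows from a
single integer seed through `numpy.random.default_rng`; identical seeds
give byte-identical outputs, which the end-to-end CLI determinism test
asserts file-by-file.

## Known limitations

Single-exon gene models: no splicing, no intron/exon ambiguity, and the
exon/intron feature assignment degenerates to exonic/intergenic on the
shipped annotations (the interfaces accept intron intervals when an
annotation provides them). Uniform base composition: real genomes are
GC-structured, so the analytic random-match null understates real-data
match rates. The generator plants no chimeras, fusion artifacts,
quality-score structure, or PCR-family errors beyond exact duplicates and
i.i.d. substitutions. The SNP benchmark inherits whatever calling biases
its input VCFs carry; the internal caller is deliberately minimal.
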