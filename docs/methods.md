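# Methods

This note records the models, parameter choices and numerical decisions
behind `spaceseq`, and what the synthetic fixtures do and do not establish
about real data.

## Input model and coordinates

The toolkit starts downstream of alignment.  Its inputs are (a) a
barcode-resolved alignment stream (SAM text) whose records carry corrected
spot barcodes (`CB`, 16 nt) and UMIs (`UB`, 12 nt), (b) a conventional
genome alignment of the same reads, (c) a tissue-position list, (d) a
reference genome, (e) a BED blacklist, (f) BED-like gene/TSS annotations.
Only the single-end genomic read is informative for accessibility; its 5′
end is the Tn5 insertion site.

All intervals are 0-based half-open, matching the fragments-file
convention, with one deliberate exception: mitochondrial variant positions
are reported 1-based to match mtDNA nomenclature.  Barcode and UMI lengths
are module constants (16/12) and overridable.

## Duplicate removal

Reads are grouped by (barcode, contig, strand, 5′ position), where the 5′
position of a reverse-strand read is `pos + aligned_length − 1`.  Position
is part of the key because identical barcode+UMI pairs at different sites
are distinct molecules.  Within a group, UMIs are clustered with the
directional network rule: an edge from the higher-count UMI A to B exists
when they differ at exactly one base and `count(A) ≥ 2·count(B) − 1`;
components reachable from the highest-count root collapse into it.  Ties in
count break toward the lexicographically smaller UMI, and the retained
representative is the member record with the smallest (pos, read_name), so
output is fully deterministic.  An `exact` mode (no merging) exists for
debugging.

Two caveats are documented rather than hidden.  First, directional merging
is not strictly idempotent: a merge can raise a cluster's multiplicity
enough that a second application would merge further in contrived count
configurations.  Exact-mode deduplication is idempotent unconditionally
(property-tested); directional idempotency holds on the simulated regimes
we test (≤ 20 % UMI error).  Second, equivalence with the directional rule
is verified against a brute-force network implementation exhaustively for
all groups of ≤ 4 UMIs with counts ≤ 5, and on random groups.

## Fragments and insertion counting

Each deduplicated read becomes a synthetic paired-end fragment
`[pos + s₊, pos + aligned_length + s₋)` with the Tn5 shift defaulting to
(s₊, s₋) = (+4, −5); the same formula serves both strands, since +4
corrects a plus-strand 5′ end and −5 a minus-strand 5′ end, whichever of
the two ends is real for the given read.  The other end is synthetic — the
end of the trimmed alignment — and this is a known bias: fragment "ends"
are not all true insertions.  Downstream counting nevertheless uses both
ends by default for compatibility with fragments-file consumers; a
`start`-only mode is available.  Records whose shifted interval collapses
(alignments shorter than |s₊| + |s₋|) are dropped and counted.

Counting unit: one unique fragment contributes one insertion per end.  The
`count` column records how many reads collapsed into the fragment; it is
bookkeeping, not a weight — except in the mitochondrial-fraction QC metric,
which is read-weighted by construction.

QC per spot (fragment count, TSS enrichment, mitochondrial fraction) is
reported but never used to drop barcodes; retention policy is the caller's.

## TSS enrichment

Insertions are aggregated into a strand-oriented profile over ±2,000 bp of
every TSS, normalized by the mean count in the outermost 100 bp of each
flank.  The score is the normalized profile averaged over ±50 bp of the
TSS.  The center average (rather than the single base at offset 0) is a
numerical necessity: at realistic depths the single-base profile value is
Poisson with single-digit counts, and the score would be dominated by shot
noise; a ±50 bp average has a few-percent standard error at 10⁴ insertions
while still sitting entirely inside the accessible region around an active
TSS.  Barcodes with zero flank signal score 0 with a warning rather than
dividing by zero.

## Tile and gene matrices, concordance

Tiles are fixed 5-kb bins per contig (the last tile may be short); the
matrix is sparse barcode × tile with grand total equal to the number of
insertion events — a conservation law the tests enforce.  Gene scores are
transparent insertion counts over the gene body plus 2 kb upstream of the
TSS, strand-aware, with overlapping genes each receiving shared
insertions.  This is deliberately *not* a distance-decay gene activity
model; it is additive over fragment streams and easy to reason about, at
the cost of ignoring long-range regulatory signal.

Concordance between accessibility gene scores and expression normalizes
each barcode to counts per 10,000, computes per-cluster means, and for
every cluster pair a two-sided rank-sum test (normal approximation) plus a
log₂ fold change of means with pseudocount 1.  A gene passes when any pair
reaches p ≤ 0.05 with |log₂FC| ≥ 1 in either modality; no multiple-testing
correction is applied — the filter is defined on raw p-values.  The test
choice (rank-sum) is an assumption; the cross-modality summary is the
Pearson correlation of per-cluster means.

## Copy number from background accessibility

Windows are 3 Mb sliding in 1-Mb steps.  Per contig, only full-width
windows are emitted (a contig shorter than one window contributes a single
truncated window).  GC is computed over non-N, non-blacklisted bases;
those bases are likewise excluded from the insertion-density denominator,
and windows more than half masked are dropped.

For each window the background is the 200 windows nearest in |ΔGC|
genome-wide, excluding the window itself and anything genomically
overlapping it — nearest-in-GC rather than genomic neighbors, because an
amplified locus would contaminate the background of its own neighborhood.
The log₂ fold change aggregates per-pair ratios
`log2((d_w + ε)/(d_b + ε))` with ε = 1/effective_length of the focal
window, which keeps the log defined for empty windows and cancels exactly
when densities are equal.  The default aggregation is a 10 %-per-tail
trimmed mean: identical to the plain mean whenever the background is
homogeneous (including the diploid-baseline identity CN = 2·2⁰ = 2), and
robust to the handful of amplified windows that inevitably leak into
GC-matched backgrounds when the genome is small relative to the amplicon.
Plain `mean`, `median` and `ratio_of_means` modes are provided.  The
diploid baseline `CN = 2·2^log2FC` is applied genome-wide; there is no
ploidy correction for sex chromosomes.

Gene CN is the unweighted mean over windows overlapping the gene by ≥ 1 bp.
Consequence worth knowing: genes within one window-width of an amplicon
boundary are diluted by partially amplified windows; recovery is unbiased
only when the amplicon is wide relative to the 3-Mb window.

Per-spot CN has no canonical definition; this package's construction is
`2 · (amplicon insertions-per-bp) / (background insertions-per-bp)` per
barcode, over the window footprint minus the amplicon.  It is invariant to
per-spot depth; barcodes with zero background signal are NaN (undefined),
not zero.

## Mitochondrial variants

Allele counts are per (barcode, strand, base, position) over every aligned
base, with an optional base-quality floor.  For each candidate
substitution, the strand correlation is the Pearson correlation between
forward- and reverse-strand alternate counts across barcodes covered at the
site; it is undefined — and the variant fails — when either strand's counts
are constant or fewer than 5 barcodes carry the allele (a guard against
spurious correlation at tiny n; raw counts by default, frequencies
optional).  Pass filter: correlation ≥ 0.25.  Heteroplasmy per spot is
alt/total at the site, NaN at zero coverage.  The filter works because a
genuine variant's two strands both track the spot's mtDNA content and
heteroplasmy, while a strand artifact by construction cannot.

This is a re-implementation of the stated core of single-cell mtDNA
genotyping (stranded per-barcode counts, strand-concordance filter,
per-cell heteroplasmy), not of any external tool's full feature set; no
coverage smoothing or variance-mean metrics are computed.  NUMT
contamination is an upstream alignment concern; the simulator can inject
misassigned reads to probe robustness instead.

## The synthetic-data generator

`simulate()` emits pre-aligned reads (SAM text) rather than FASTQ because
alignment is out of scope; this closes the fixture loop.  One seeded
generator drives all draws; the mitochondrial reference uses a sub-seed
derived only from (seed, length) so callers can inspect it before choosing
variant alleles.  Same seed ⇒ byte-identical outputs.

Study conditions baked into the defaults:

- Nuclear reads are uniform over the genome; inside the amplicon the
  sampling rate is multiplied by true_cn/2 for affected spots.  Reads per
  spot are fixed, so bulk amplicon signal under partial clonality reflects
  both the clone fraction and per-spot depth normalization (the README's
  worked example quantifies this).
- Duplicates re-emit an existing molecule under a fresh read name with the
  configured probability; UMI errors mutate exactly one base.
- Per-spot mitochondrial depth varies by a lognormal factor (σ = 0.35) and
  per-spot heteroplasmy is Beta-distributed around the variant mean
  (concentration 30, recorded per spot in the truth tables).  Both reflect
  real tissue — mtDNA content and heteroplasmy are never uniform across
  spots — and together they are what makes the two strands of a genuine
  variant co-vary.  With strictly constant depth and heteroplasmy the two
  strands' binomial draws would be independent and the strand filter would
  have no signal to detect, for real variants and artifacts alike.
- Strand bias b places alternate reads on the forward strand with
  probability `min(1, 2bh)` and reverse with `min(1, 2(1−b)h)`; b = 0.5 is
  balanced, b = 1 a pure artifact.
- The mitochondrial contig is a 1.2-kb stand-in at mtDNA-like GC, not the
  16.6-kb molecule, keeping 100× per-spot pileups desk-sized.

What the fixtures do not emulate: realistic fragment-length or chromatin
structure, peak structure, mappability variation, barcode bead errors, or
NUMT alignment physics.  Passing tests therefore establish algorithmic
correctness and statistical calibration under the stated generative model,
not end-to-end performance on tissue data.

## Problem sizes used in tests

Recovery tests run at deliberately modest scale: 100-Mb genomes (10
contigs) for copy number, ~16–24 k reads per pipeline fixture, 40 spots at
~100× mitochondrial coverage, 10⁴ insertions for TSS calibration.  These
sizes put Monte-Carlo error well inside each asserted tolerance (e.g.
window CN at ≥ 300 molecules/window has ≈ 6 % relative error against a
±20 % band) while keeping the full suite under a minute of simulation
time.

## Known limitations

- Gene scores ignore distance decay; do not compare their absolute values
  with decay-based gene activity models.
- Bulk window CN under partial clonality estimates the mixture, not the
  clone; use the per-spot estimator to resolve populations.
- The strand-correlation filter needs cross-spot variance in mtDNA signal;
  in a hypothetical perfectly homogeneous sample it would reject true
  variants (correlation undefined or ≈ 0).
- Fragment compression/indexing (bgzip/tabix) is out of the correctness
  contract; all I/O contracts are defined on plain text.
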