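# Methods

## Problem and signal model

Extrachromosomal circular DNA (ecDNA) and its chromosomally reintegrated
form (homogeneously staining regions, HSRs) carry amplified oncogenes at
tens to hundreds of copies. Because ecDNA chromatin is less compacted
than chromosomal chromatin, ATAC-seq over an ecDNA+ sample shows two
joint signals that this package exploits:

1. **contiguous stretches of strongly elevated coverage** over every
   genomic segment incorporated in the amplicon, and
2. **structural-variant junctions** between segment ends: read pairs
   whose mates map abnormally far apart or to different chromosomes
   (discordant pairs), and reads that align in two pieces across a
   junction (split reads, recorded by the aligner as a primary
   alignment plus a supplementary alignment referenced in the `SA`
   tag).

Detection proceeds in five stages: abnormal-read extraction, breakpoint
building, coverage-thresholded region growth, graph assembly, and
(optionally) cell-barcode attribution.

## Abnormal-read extraction

A primary, mapped, paired record with mapping quality ≥ `mapq_min`
(default 1) and no duplicate flag is

* a **split read** when it carries an `SA` tag;
* part of a **discordant pair** when its mates map to different
  chromosomes, or when the pair's reference span
  `max(alignment ends) − min(alignment starts)` exceeds
  `fragment_length_threshold` (default 1000 bp, suited to the
  sub-kilobase fragment sizes of standard ATAC libraries; raise it for
  long-fragment protocols).

The two classes are independent — a split read whose own pair also
spans abnormally contributes to both streams, because the two evidence
types are counted separately downstream and dropping either would
weaken support. Same-chromosome spans are taken from the template
length (TLEN) field, with a fallback to the mate CIGAR (`MC` tag). Both
streams are also written as sorted, indexed BAMs so a run can later be
resumed in `from_abnormal` mode (only primary records are written to
the split BAM; the supplementary half of each split alignment is fully
reconstructable from its `SA` tag).

## Breakpoint building

**Split reads.** The clipped end of a local alignment abuts the
junction: a leading soft/hard clip places the breakpoint at the
alignment start, a trailing clip at the alignment end (start plus
reference-consuming CIGAR length). The same rule applies to the
supplementary alignment parsed from the `SA` tag. Orientation is
encoded per side as alignment strand XOR clip side; it is reported but
not used for filtering. Identical breakpoint tuples aggregate with
summed support; neighboring tuples within `merge_range` (default
1000 bp) of each other on both sides merge by single linkage, keeping
the highest-support member's coordinates. When both read ends are
clipped, the longer clip decides the junction side and the read is
counted.

**Discordant pairs.** Each mate's leftmost alignment coordinate seeds
an interval of ±`cluster_halfwidth` (default 500 bp). Two pairs join
one cluster when their a-side intervals overlap *and* their b-side
intervals overlap — two-sided single linkage, computed as connected
components of the dual-overlap relation. One-sided merging was
rejected because it chains unrelated junctions that happen to share one
locus. Cluster intervals are the unions of member intervals; support is
the member count. Loci are canonically ordered (chromosome, then
coordinate) so a pair and its mirror are one object.

A split pair whose two exact coordinates fall inside a cluster's two
intervals is folded into that cluster (evidence `both`, summed support,
exact coordinates retained), since both describe the same junction.

## Amplification threshold and region growth

The genome-wide mean depth is estimated from `depth_samples` (default
2000) random 1-kb windows drawn length-weighted across chromosomes
under a fixed seed; an exact full-pass mode (total aligned bases over
genome length) is available. The amplification threshold is

```
covt = covt_multiplier × genome_mean        (default multiplier 3.0)
```

a multiple of the mean rather than an absolute depth so that the gate
scales with library size. Depth over any interval counts each aligned
base of primary, non-duplicate records once.

From the midpoint of each breakpoint locus (interval-valued cluster
pairs are seeded first, then split-only pairs), windows of
`window_size` (default 1000 bp; smaller windows refine boundaries at
proportional cost) extend independently upstream and downstream:

* a window whose own mean depth is ≥ covt is accepted;
* a window below covt is *tolerated* while the running mean of the
  region including it stays ≥ covt, for at most `max_dip_windows`
  (default 2) consecutive windows — this bridges short local dips
  inside an amplicon;
* otherwise the direction stops, and any trailing tolerated windows
  are trimmed, so the reported boundary is always the last
  above-threshold window.

The trimming cap is a deliberate design choice: an unbounded
running-mean rule would let a long, deeply amplified region drag the
extension tens of windows into background coverage before the
cumulative mean decays, biasing every boundary outward; with trimming,
boundaries land within one window of the true depth step. Growth
returns nothing when even the initial window fails covt. Regions are
unions of whole windows, so boundaries are quantized at `window_size`;
coordinates are 0-based half-open, and the reported `length` column is
exactly `end − start`.

Overlapping grown intervals from different seeds are unified so output
regions are pairwise disjoint. Regions shorter than
`min_region_length` (default 3000 bp) are discarded; a breakpoint-pair
side whose locus has no retained region is left unassigned, pairs with
both sides unassigned are dropped, and pairs connecting the same two
regions merge with summed support. Because region edges are
window-quantized while breakpoints are base-precise, a side is assigned
by midpoint containment with a fallback to the best-overlapping region
within one window of the locus.

## Co-amplification graph

Retained regions are nodes; merged pairs with both sides assigned are
weighted edges (weight = support). Connected components are the
co-amplified structures; the component score is the total support of
its member pairs. Within components of ≤ 12 nodes all simple cycles
are enumerated (beyond that a fundamental cycle basis is reported with
a warning — exhaustive enumeration is exponential). The **maximum
circle** — the candidate ecDNA — is the simple cycle maximizing total
genomic length of its member regions (biologically, the reconstructed
circle size), with ties broken by summed edge support and then by
lexicographically smallest canonical node sequence. A pair whose two
breakpoints fall in a single region is the simplest circularization
topology; it is kept as a node attribute and reported as a single-node
cycle of rank 0.

## Annotation

Gene rows of a user-supplied GTF (gzip accepted; `transcript` rows,
deduplicated by gene name with unioned spans, are the fallback when no
`gene` rows exist) are indexed by interval tree. A region is annotated
with every gene it overlaps by ≥ 1 bp, strand ignored (amplicons are
strand-agnostic), listed in genomic start order. Chromosome naming is
harmonized by stripping a `chr` prefix on either side; no further
alias table is attempted.

## Single-cell attribution

Detection always runs on the pooled reads; barcodes are a post-hoc
projection. A barcoded abnormal read supports a pair when its junction
coordinates (split) or both mate start sites (discordant) fall inside
the pair's two loci, padded by `merge_range` to absorb representative-
coordinate shifts from neighbor merging. Barcodes aggregate per pair
and propagate to the regions and components the pair connects; a
configurable floor (default 1 read per barcode-pair) applies. Reads
without the barcode tag (default `CB`) are counted and excluded; if
*no* abnormal read carries a barcode in single-cell mode, the run
fails with advice to check the tag name.

## Synthetic fixtures

The generator writes alignments directly (no aligner), which keeps
CIGAR strings, `SA` tags and mate fields exactly controlled and tests
the detection algorithms in isolation from alignment behavior. The
default scenario, used by the test suite and the acceptance script,
is a 2 × 500 kb random reference holding:

* a **main circle** of three segments (chr1:100–140 kb,
  chr1:300–330 kb, chr2:150–180 kb) at 10× the 5× background —
  amplified fraction ≈ 0.1 of the genome, which keeps
  covt = 3 × genome mean (≈ 27–29×) comfortably between background
  (5×) and amplicon (50×) depth, so seed windows straddling a segment
  boundary still clear the gate;
* a **short decoy circle** of two 2.0 kb segments at the same 50×
  depth — above covt but below `min_region_length`, so its junction
  pairs are dropped; 2.0 kb (rather than, say, 2.5 kb) makes the
  exclusion robust to window quantization, since no grid offset lets
  three 1-kb windows over a 2.0 kb plateau all pass covt;
* a **cold circle** of two 20 kb segments with junction reads but
  background depth, exercising the covt gate.

Read length is 100 bp, fragment length 400 ± 60 bp (ATAC
di-nucleosome scale; concordant spans stay far below the 1000 bp
threshold). Each junction receives 40 discordant-only pairs and 12
split reads; a split read's mate maps past the junction, so split
pairs are also discordant — the truth file accounts for both. In
single-cell mode, 100 cells are simulated with a planted positive
fraction of 0.2; background reads draw barcodes from all cells, while
amplicon and junction reads draw from positives only, with junction
reads dealt round-robin so every positive cell supports every
junction.

The simulation covers coverage steps, junction mechanics and barcode
structure, but not Tn5 insertion bias, peak structure, GC bias,
fragment-size periodicity or sequencing error — so passing tests
demonstrate algorithmic correctness on the stated signal model, not
end-to-end performance on real ATAC-seq libraries.

## Numerical and degenerate-input choices

* Spans compare strictly (`span > threshold`); raising the threshold
  can only shrink the discordant set.
* Clustering and merging are order-invariant: components are computed
  over a canonical sort, and all outputs are canonically sorted, so
  TSVs are byte-identical across runs and thread counts.
* Per-chromosome classification parallelizes over threads; results
  merge in header order. Inter-chromosomal pairs are emitted exactly
  once, by the mate with the smaller (chromosome, coordinate).
* Empty inputs degrade explicitly: an unindexed or unsorted BAM and an
  empty BAM are errors naming the problem; a BAM without pairs yields
  an empty discordant stream with a warning; empty pair lists yield
  header-only outputs.
* The run manifest (parameters, versions, per-stage counts and
  timings) is written on success and on failure.

## Known limitations

* covt's construction is a multiplier of the genome mean; on genomes
  where amplicons occupy a large fraction of sequence the mean (and
  hence covt) inflates, which can gate true amplicons — a blacklist or
  robust (median-based) estimator would mitigate this.
* Region boundaries are window-quantized; sub-window boundary
  precision is not attempted.
* No GC correction, duplicate marking, or absolute copy-number
  estimation; orientation of breakpoints is reported but unused, so
  path/sequence reconstruction of the circle is out of scope.
* Cycle enumeration is exhaustive only up to 12-node components.
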