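# ecamp

Detection of ecDNA/HSR co-amplified regions from bulk and single-cell
ATAC-seq alignments.

Tumor cells frequently amplify oncogenes on extrachromosomal circular
DNA (ecDNA) or its chromosomally reintegrated form (homogeneously
staining regions, HSRs). Because ecDNA chromatin is unusually open,
ATAC-seq data carries a double signature of these structures:
megabase-scale runs of elevated coverage over every amplified segment,
and structural-variant junctions between segment ends visible as
discordant read pairs and split (chimeric) reads. `ecamp` turns a
coordinate-sorted BAM into a catalog of amplified regions, the
breakpoint pairs connecting them, and a genome-wide **breakpoint
graph** whose connected components are co-amplified structures and
whose cycles are candidate circular ecDNA elements. For single-cell
ATAC-seq, it additionally reports which cell barcodes support each
structure.

## Method at a glance

For a BAM with mean genome depth μ and threshold `covt = k·μ`
(default k = 3):

1. **Extract** split reads (`SA`-tagged primaries) and discordant
   pairs (inter-chromosomal, or reference span > 1000 bp) into two
   abnormal-read BAMs.
2. **Breakpoints.** Split-read CIGAR clipping gives exact junction
   coordinates (leading clip → alignment start, trailing clip →
   alignment end), aggregated by support; discordant mate starts
   ±500 bp are clustered by two-sided single linkage into
   interval-valued breakpoint pairs; the two evidence types are merged
   where they coincide.
3. **Regions.** From each breakpoint locus midpoint, 1-kb windows grow
   outward while window depth ≥ covt (short dips bridged while the
   running mean holds); regions < 3 kb are discarded along with the
   pair sides they would anchor.
4. **Graph.** Regions become nodes, breakpoint pairs weighted edges;
   components are scored by total abnormal-read support, all simple
   cycles are enumerated and the **maximum circle** (largest total
   genomic length) is reported per component.
5. **Annotate / attribute.** Regions gain overlapping gene names from
   a GTF; in single-cell mode, barcodes of junction-supporting reads
   are projected onto pairs, regions and components.

See `docs/methods.md` for the full model, parameter semantics and
limitations.

## Worked example

`ecamp` ships a simulator that plants circular amplicons with exact
junction geometry, so the whole pipeline can be exercised without any
external data:

```sh
ecamp make-fixture --out-dir fixture --seed 17
ecamp run --bam fixture/reads.bam --out-dir run --no-images
```

The fixture plants a three-segment circle
(chr1:100,000–140,000 → chr1:300,000–330,000 → chr2:150,000–180,000)
at 10× over a 5× background, plus two decoy structures that should be
rejected. The run prints:

```
regions: 3  pairs: 3  components: 1  -> run
```

and `run/regions.tsv` contains (coordinates are 0-based half-open, so
`length = end − start` exactly):

```
region_id  chrom  start   end     length  mean_depth  genes
1          chr1   99670   139670  40000   50.225
2          chr1   299691  330298  30607   49.542
3          chr2   149681  180271  30590   49.481
```

Each planted segment is recovered within one 1-kb window of its true
boundaries at the planted ~50× depth. `run/breakpoints.tsv` holds the
three junction pairs (support 64 each: 40 discordant-only pairs, 12
split reads and their 12 discordant mates per junction),
`run/components.tsv` one component with score 192, and
`run/cycles.tsv` its single 3-node cycle — the reconstructed circle.
The decoy structures (a 2 kb amplified circle and a background-depth
junction) are absent, filtered by the minimum region length and the
coverage threshold respectively. With `--single-cell` on a barcoded
fixture (`make-fixture --n-cells 100`), `run/cell_barcodes.tsv` lists
exactly the 20 planted ecDNA-positive cells.

## Layout

```
src/ecamp/
  extract.py      abnormal-read classification and BAM output
  breakpoints.py  split-read calling, discordant clustering, merging
  coverage.py     depth accessor, genome-mean estimation, covt
  regions.py      region growth, filtering, numbering, tables
  graph.py        components, cycle enumeration, maximum circle, export
  annotate.py     GTF gene annotation
  single_cell.py  barcode attribution
  simulate.py     planted-amplicon read simulator + truth files
  pipeline.py     orchestration, threading, run manifest
  cli.py          `ecamp run`, `ecamp make-fixture`
```
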