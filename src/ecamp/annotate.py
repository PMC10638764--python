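"""Gene annotation of amplified regions from a GTF file.

Feature rows of type "gene" (fallback: "transcript", deduplicated by
name) are indexed by interval; a region is annotated with every gene it
overlaps by at least one base, strand ignored. Chromosome naming is
harmonized by stripping any "chr" prefix on both sides, so a GTF using
"1" annotates a BAM using "chr1" and vice versa.
"""

from __future__ import annotations

import gzip
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import gffutils
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    name: str


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class GeneIndex:
    """Interval index of gene records keyed by normalized chromosome."""

    def __init__(self, records):
        self.records = list(records)
        self._trees = {}
        for rec in self.records:
            self._trees.setdefault(_norm_chrom(rec.chrom), IntervalTree()).addi(
                rec.start, rec.end, rec
            )

    def __len__(self):
        return len(self.records)

    def overlapping(self, chrom: str, start: int, end: int):
        """Genes overlapping [start, end) by >= 1 bp, sorted by start."""
        tree = self._trees.get(_norm_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.start, g.end, g.name))


def load_gtf(path, feature_types=("gene",)) -> GeneIndex:
    """Build a GeneIndex from a (possibly gzipped) GTF.

    Rows of the first feature type with any parseable entries win;
    "transcript" rows (deduplicated by gene name) are the fallback when
    no "gene" rows exist. Rows lacking both gene_name and gene_id are
    skipped and counted on the returned index as ``n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GTF not found: {path}")
    tmp = None
    try:
        if path.suffix == ".gz":
            tmp = tempfile.NamedTemporaryFile(
                mode="wb", suffix=".gtf", delete=False
            )
            with gzip.open(path, "rb") as src:
                shutil.copyfileobj(src, tmp)
            tmp.close()
            gtf_path = tmp.name
        else:
            gtf_path = str(path)
        db = gffutils.create_db(
            gtf_path,
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    finally:
        if tmp is not None:
            Path(tmp.name).unlink(missing_ok=True)

    n_skipped = 0

    def records_of(ftype):
        nonlocal n_skipped
        out = []
        for feat in db.features_of_type(ftype):
            name = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [None])[0]
            if not name:
                n_skipped += 1
                continue
            # GTF is 1-based inclusive; convert to 0-based half-open.
            out.append(
                GeneRecord(feat.seqid, feat.start - 1, feat.end, feat.strand or ".", name)
            )
        return out

    records = []
    for ftype in feature_types:
        records = records_of(ftype)
        if records:
            break
    if not records:
        seen = {}
        for rec in records_of("transcript"):
            prev = seen.get(rec.name)
            if prev is None:
                seen[rec.name] = rec
            else:  # widen to the union span of the gene's transcripts
                seen[rec.name] = GeneRecord(
                    prev.chrom,
                    min(prev.start, rec.start),
                    max(prev.end, rec.end),
                    prev.strand,
                    prev.name,
                )
        records = list(seen.values())
    if not records:
        raise ValueError(f"no parseable gene or transcript rows in {path}")
    index = GeneIndex(records)
    index.n_skipped = n_skipped
    return index


def annotate_regions(regions, gene_index: GeneIndex):
    """Fill each region's ``genes`` with overlapping gene names, in
    genomic start order. Pure: returns the same region objects."""
    for region in regions:
        region.genes = [
            g.name for g in gene_index.overlapping(region.chrom, region.start, region.end)
        ]
    return regions
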