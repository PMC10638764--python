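"""Partition BAM records into split-read and discordant-pair evidence.

A primary, mapped, paired record is a *split read* when it carries an SA
(supplementary alignment) tag, and belongs to a *discordant pair* when
its mates map to different chromosomes or span more of the reference
than the fragment-length threshold. The two classes are independent: a
split read whose pair is also abnormally spaced contributes to both
streams.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pysam

from .params import DetectionParameters

#: Sentinel span for mates on different chromosomes.
INTERCHROM_SPAN = -1

_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    length = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in _REF_CONSUMING:
                length += int(num)
            num = ""
    return length


@dataclass
class SplitAlignment:
    """Primary alignment plus its supplementary locus parsed from the SA tag."""

    read_name: str
    chrom: str
    start: int  # 0-based
    end: int
    strand: str
    cigar: str
    sa_chrom: str
    sa_pos: int  # 0-based
    sa_strand: str
    sa_cigar: str
    barcode: Optional[str] = None


@dataclass
class DiscordantPair:
    """Read pair with abnormal reference span, loci in canonical order."""

    read_name: str
    chrom_a: str
    start_a: int
    end_a: int
    strand_a: str
    chrom_b: str
    start_b: int
    end_b: int
    strand_b: str
    span: int  # INTERCHROM_SPAN when chrom_a != chrom_b
    barcode: Optional[str] = None

    @classmethod
    def from_loci(cls, read_name, locus1, locus2, span, barcode=None):
        a, b = sorted((locus1, locus2), key=lambda l: (l[0], l[1]))
        return cls(read_name, *a, *b, span=span, barcode=barcode)


def _check_bam(bam_path) -> None:
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise FileNotFoundError(f"BAM not found: {bam_path}")
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        so = bam.header.to_dict().get("HD", {}).get("SO", "unknown")
        if so != "coordinate":
            raise ValueError(
                f"{bam_path} is not coordinate-sorted (SO={so}); sort it first"
            )
        if not bam.has_index():
            raise FileNotFoundError(
                f"missing BAM index for {bam_path}: expected {bam_path}.bai "
                f"(run samtools index)"
            )


def _barcode_of(rec, params: DetectionParameters) -> Optional[str]:
    if rec.has_tag(params.barcode_tag):
        return rec.get_tag(params.barcode_tag)
    if params.single_cell and ":" in rec.query_name:
        return rec.query_name.rsplit(":", 1)[1]
    return None


def _parse_sa(tag: str):
    first = tag.split(";")[0]
    fields = first.split(",")
    if len(fields) < 4:
        return None
    chrom, pos, strand, cigar = fields[0], fields[1], fields[2], fields[3]
    try:
        pos0 = int(pos) - 1
    except ValueError:
        return None
    if strand not in "+-" or not cigar:
        return None
    return chrom, pos0, strand, cigar


def _pair_span(rec) -> int:
    """Reference span max(ends) - min(starts) of the two primary alignments."""
    if rec.reference_id != rec.next_reference_id:
        return INTERCHROM_SPAN
    if rec.template_length != 0:
        return abs(rec.template_length)
    mate_len = (
        cigar_reference_length(rec.get_tag("MC"))
        if rec.has_tag("MC")
        else (rec.reference_length or rec.query_length)
    )
    left = min(rec.reference_start, rec.next_reference_start)
    right = max(rec.reference_end, rec.next_reference_start + mate_len)
    return right - left


def _is_pair_leader(rec) -> bool:
    """True for exactly one record of a pair, for single emission."""
    here = (rec.reference_id, rec.reference_start)
    there = (rec.next_reference_id, rec.next_reference_start)
    if here != there:
        return here < there
    return rec.is_read1


def classify_reads(
    bam_path,
    params: DetectionParameters,
    contig: Optional[str] = None,
    sink=None,
):
    """Single pass over a coordinate-sorted BAM.

    Returns (splits, discordant_pairs, summary). ``sink``, when given,
    receives the raw records: ``sink.split(rec)`` for each split-read
    primary and ``sink.discordant(rec)`` for each record belonging to a
    discordant pair (both mates, as encountered).
    """
    _check_bam(bam_path)
    splits, pairs = [], []
    summary = {
        "total_primary": 0,
        "split_reads": 0,
        "discordant_pairs": 0,
        "discordant_records": 0,
        "skipped_low_quality": 0,
        "skipped_unparseable_sa": 0,
        "paired_records": 0,
    }
    thr = params.fragment_length_threshold
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        iterator = bam.fetch(contig) if contig is not None else bam.fetch()
        for rec in iterator:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate or rec.mapping_quality < params.mapq_min:
                summary["skipped_low_quality"] += 1
                continue
            summary["total_primary"] += 1
            if rec.is_paired:
                summary["paired_records"] += 1

            if rec.has_tag("SA"):
                parsed = _parse_sa(rec.get_tag("SA"))
                if parsed is None:
                    summary["skipped_unparseable_sa"] += 1
                else:
                    sa_chrom, sa_pos, sa_strand, sa_cigar = parsed
                    splits.append(
                        SplitAlignment(
                            read_name=rec.query_name,
                            chrom=rec.reference_name,
                            start=rec.reference_start,
                            end=rec.reference_end,
                            strand="-" if rec.is_reverse else "+",
                            cigar=rec.cigarstring,
                            sa_chrom=sa_chrom,
                            sa_pos=sa_pos,
                            sa_strand=sa_strand,
                            sa_cigar=sa_cigar,
                            barcode=_barcode_of(rec, params),
                        )
                    )
                    summary["split_reads"] += 1
                    if sink is not None:
                        sink.split(rec)

            if not rec.is_paired or rec.mate_is_unmapped:
                continue
            span = _pair_span(rec)
            if span != INTERCHROM_SPAN and span <= thr:
                continue
            summary["discordant_records"] += 1
            if sink is not None:
                sink.discordant(rec)
            if _is_pair_leader(rec):
                mate_len = (
                    cigar_reference_length(rec.get_tag("MC"))
                    if rec.has_tag("MC")
                    else (rec.reference_length or rec.query_length)
                )
                locus1 = (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                locus2 = (
                    rec.next_reference_name,
                    rec.next_reference_start,
                    rec.next_reference_start + mate_len,
                    "-" if rec.mate_is_reverse else "+",
                )
                pairs.append(
                    DiscordantPair.from_loci(
                        rec.query_name, locus1, locus2, span, _barcode_of(rec, params)
                    )
                )
                summary["discordant_pairs"] += 1
    if summary["paired_records"] == 0:
        warnings.warn(f"no paired reads in {bam_path}; discordant stream is empty")
    return splits, pairs, summary


class _BamSink:
    def __init__(self, header, split_path, discordant_path):
        self._split = pysam.AlignmentFile(str(split_path), "wb", header=header)
        self._discordant = pysam.AlignmentFile(str(discordant_path), "wb", header=header)

    def split(self, rec):
        self._split.write(rec)

    def discordant(self, rec):
        self._discordant.write(rec)

    def close(self):
        self._split.close()
        self._discordant.close()


def write_abnormal_bams(bam_path, out_dir, params: DetectionParameters, prefix="abnormal"):
    """Write ``<prefix>.split.bam`` / ``<prefix>.discordant.bam`` (sorted,
    indexed) plus ``extraction_summary.tsv``.

    Returns (split_bam, discordant_bam, summary).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory not writable: {out_dir}")

    split_bam = out_dir / f"{prefix}.split.bam"
    discordant_bam = out_dir / f"{prefix}.discordant.bam"
    tmp_split = out_dir / f"{prefix}.split.unsorted.bam"
    tmp_disc = out_dir / f"{prefix}.discordant.unsorted.bam"

    with pysam.AlignmentFile(str(bam_path), "rb") as src:
        sink = _BamSink(src.header, tmp_split, tmp_disc)
    try:
        _, _, summary = classify_reads(bam_path, params, sink=sink)
    finally:
        sink.close()
    for tmp, final in ((tmp_split, split_bam), (tmp_disc, discordant_bam)):
        pysam.sort("-o", str(final), str(tmp))
        tmp.unlink()
        pysam.index(str(final))

    with open(out_dir / "extraction_summary.tsv", "w") as fh:
        fh.write("metric\tcount\n")
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    return split_bam, discordant_bam, summary


def load_abnormal_bams(split_bam, discordant_bam, params: DetectionParameters):
    """Rebuild the evidence streams from previously written abnormal BAMs.

    Used by ``from_abnormal`` mode to resume after extraction.
    """
    splits, _, _ = classify_reads(split_bam, params)

    pairs = []
    pending = {}
    n_unmatched = 0
    with pysam.AlignmentFile(str(discordant_bam), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            key = rec.query_name
            if key not in pending:
                pending[key] = (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    _barcode_of(rec, params),
                )
            else:
                chrom1, s1, e1, strand1, bc = pending.pop(key)
                locus1 = (chrom1, s1, e1, strand1)
                locus2 = (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                if chrom1 != rec.reference_name:
                    span = INTERCHROM_SPAN
                else:
                    span = max(e1, rec.reference_end) - min(s1, rec.reference_start)
                pairs.append(
                    DiscordantPair.from_loci(
                        key, locus1, locus2, span, bc or _barcode_of(rec, params)
                    )
                )
    n_unmatched = len(pending)
    if n_unmatched:
        warnings.warn(f"{n_unmatched} unmatched mates in {discordant_bam}")
    return splits, pairs
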