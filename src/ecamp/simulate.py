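"""Synthetic ATAC-seq fixtures with planted circular amplicons.

Reads are written directly as alignments (no realignment step), so CIGAR
strings, SA tags and mate coordinates are exactly controlled and the
detection algorithms are isolated from aligner behavior. The signal model
emulated is: uniform paired-end background coverage, contiguous
higher-depth segments for each planted circle, junction-straddling read
pairs (discordant on the reference) and junction-overlapping split reads
(primary + supplementary alignment with an SA tag) for every adjacent
segment junction, including the circle's wrap-around junction. In
single-cell mode, cell-barcode tags are drawn from a pool of cells of
which only a planted positive fraction carries amplicon and junction
reads.

Not modeled: Tn5 insertion bias, peak structure, GC bias, fragment-size
periodicity, sequencing errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Segment:
    """Half-open genomic interval with a traversal orientation."""

    chrom: str
    start: int
    end: int
    orientation: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self}")
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be + or -, got {self.orientation}")

    @property
    def length(self) -> int:
        return self.end - self.start

    # Coordinate at which a circle traversal leaves / enters this segment.
    @property
    def exit_point(self) -> int:
        return self.end if self.orientation == "+" else self.start

    @property
    def entry_point(self) -> int:
        return self.start if self.orientation == "+" else self.end


@dataclass
class CircleSpec:
    """One planted circular structure (>= 2 segments)."""

    segments: list
    copy_multiplier: float = 10.0
    n_split_per_junction: int = 12
    n_discordant_per_junction: int = 40

    def __post_init__(self):
        if len(self.segments) < 2:
            raise ValueError("a circle needs at least 2 segments")

    @property
    def junctions(self):
        """(exiting segment, entering segment) per junction, wrap included."""
        k = len(self.segments)
        return [(self.segments[i], self.segments[(i + 1) % k]) for i in range(k)]


@dataclass
class EcdnaSpec:
    """Full simulation scenario: background plus planted circles."""

    circles: list = field(default_factory=list)
    background_depth: float = 5.0
    read_length: int = 100
    fragment_mean: int = 400
    fragment_sd: int = 60
    n_cells: int = 0
    fraction_positive: float = 0.2
    seed: int = 17

    def __post_init__(self):
        if self.fragment_mean < 2 * self.read_length + 20:
            raise ValueError("fragment_mean must exceed twice the read length")


def make_reference(lengths: dict, out_fasta, seed: int) -> Path:
    """Write a random-base FASTA (plus .fai) with the given chromosome lengths."""
    out_fasta = Path(out_fasta)
    rng = np.random.default_rng(seed)
    with open(out_fasta, "w") as fh:
        for name, length in lengths.items():
            if length < 1000:
                raise ValueError(f"chromosome {name} too short ({length})")
            fh.write(f">{name}\n")
            seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(out_fasta))
    return out_fasta


def default_fixture_spec(seed: int = 17, n_cells: int = 0) -> EcdnaSpec:
    """The standard planted scenario used throughout the test suite.

    A 3-segment circular amplicon at 10x the 5x background (40+30+30 kb,
    spanning both chromosomes), a short decoy circle of two 2 kb
    amplified segments (rejected by the minimum region length), and a
    "cold" circle whose junction reads are planted but whose segments
    stay at background depth (rejected by the covt gate).
    """
    main = CircleSpec(
        segments=[
            Segment("chr1", 100_000, 140_000),
            Segment("chr1", 300_000, 330_000),
            Segment("chr2", 150_000, 180_000),
        ],
        copy_multiplier=10.0,
    )
    short_decoy = CircleSpec(
        segments=[
            Segment("chr2", 300_000, 302_000),
            Segment("chr2", 320_000, 322_000),
        ],
        copy_multiplier=10.0,
    )
    cold = CircleSpec(
        segments=[
            Segment("chr1", 400_000, 420_000),
            Segment("chr2", 400_000, 420_000),
        ],
        copy_multiplier=1.0,
    )
    return EcdnaSpec(
        circles=[main, short_decoy, cold],
        background_depth=5.0,
        n_cells=n_cells,
        fraction_positive=0.2,
        seed=seed,
    )


DEFAULT_REFERENCE_LENGTHS = {"chr1": 500_000, "chr2": 500_000}


class _BamBuilder:
    """Accumulates alignment records and tracks aligned-base totals."""

    def __init__(self, header: pysam.AlignmentHeader, read_length: int, rng):
        self.header = header
        self.read_length = read_length
        self.rng = rng
        self.records = []
        self.total_aligned_bases = 0
        self._qual = pysam.qualitystring_to_array("I" * read_length)

    def _new_record(self, name, chrom, start, cigar, reverse, barcode):
        rec = pysam.AlignedSegment(self.header)
        rec.query_name = name
        rec.reference_id = self.header.get_tid(chrom)
        rec.reference_start = start
        rec.cigarstring = cigar
        rec.mapping_quality = 60
        rec.is_reverse = reverse
        rec.is_paired = True
        seq = _BASES[self.rng.integers(0, 4, size=self.read_length)].tobytes().decode()
        rec.query_sequence = seq
        rec.query_qualities = self._qual
        if barcode is not None:
            rec.set_tag("CB", barcode, "Z")
        return rec

    def add_pair(self, name, side1, side2, proper, barcode=None):
        """side = (chrom, start, cigar, reverse). Sets mate fields and MC tags."""
        r1 = self._new_record(name, *side1, barcode)
        r2 = self._new_record(name, *side2, barcode)
        r1.is_read1, r2.is_read2 = True, True
        for a, b in ((r1, r2), (r2, r1)):
            a.next_reference_id = b.reference_id
            a.next_reference_start = b.reference_start
            a.mate_is_reverse = b.is_reverse
            a.mate_is_unmapped = False
            a.is_proper_pair = proper
            a.set_tag("MC", b.cigarstring, "Z")
        if r1.reference_id == r2.reference_id:
            left = min(r1.reference_start, r2.reference_start)
            right = max(r1.reference_end, r2.reference_end)
            span = right - left
            for rec in (r1, r2):
                rec.template_length = span if rec.reference_start == left else -span
        self.records.extend((r1, r2))
        self.total_aligned_bases += r1.reference_length + r2.reference_length
        return r1, r2

    def add_single(self, name, side, supplementary=False, barcode=None):
        rec = self._new_record(name, *side, barcode)
        rec.is_supplementary = supplementary
        self.records.append(rec)
        self.total_aligned_bases += rec.reference_length
        return rec


def _clipped_normal(rng, mean, sd, low, high):
    value = int(round(rng.normal(mean, sd)))
    return max(low, min(high, value))


def _junction_parts(exiting: Segment, entering: Segment, k: int, read_length: int):
    """Alignment coordinates of the two parts of a junction-overlapping read.

    The read's first k bases come from the exiting segment (abutting its
    exit point), the remaining bases from the entering segment. Returns
    ((chrom, start, cigar, reverse), breakpoint) for each part, with the
    CIGAR clip placed on the junction side in reference orientation.
    """
    m = read_length - k
    if exiting.orientation == "+":
        part_a = (exiting.chrom, exiting.exit_point - k, f"{k}M{m}S", False)
    else:
        part_a = (exiting.chrom, exiting.exit_point, f"{m}S{k}M", True)
    if entering.orientation == "+":
        part_b = (entering.chrom, entering.entry_point, f"{k}S{m}M", False)
    else:
        part_b = (entering.chrom, entering.entry_point - m, f"{m}M{k}S", True)
    return part_a, part_b


def _mate_in_entering(entering: Segment, offset: int, read_length: int):
    """Reverse-complement mate aligned `offset` bases past the entry point."""
    offset = max(0, min(offset, entering.length - read_length))
    if entering.orientation == "+":
        return (entering.chrom, entering.entry_point + offset, f"{read_length}M", True)
    return (
        entering.chrom,
        entering.entry_point - offset - read_length,
        f"{read_length}M",
        False,
    )


def _mate_in_exiting(exiting: Segment, back: int, read_length: int):
    """Forward mate whose alignment ends `back` bases before the exit point."""
    back = max(0, min(back, exiting.length - read_length))
    if exiting.orientation == "+":
        return (exiting.chrom, exiting.exit_point - back - read_length, f"{read_length}M", False)
    return (exiting.chrom, exiting.exit_point + back, f"{read_length}M", True)


def simulate_reads(spec: EcdnaSpec, reference_fasta, out_bam, truth_json=None):
    """Simulate the scenario into a sorted, indexed BAM plus a truth dict.

    Returns (bam_path, truth). The truth dict (also written to
    ``truth_json`` when given) records planted segments, junction
    coordinates with expected split/discordant support, per-circle
    depths, positive barcodes and aligned-base totals.
    """
    out_bam = Path(out_bam)
    rng = np.random.default_rng(spec.seed)
    fasta = pysam.FastaFile(str(reference_fasta))
    lengths = dict(zip(fasta.references, fasta.lengths))
    fasta.close()

    for circle in spec.circles:
        for seg in circle.segments:
            if seg.chrom not in lengths or seg.end > lengths[seg.chrom]:
                raise ValueError(f"segment {seg} exceeds reference bounds")

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in lengths.items()],
        }
    )
    L = spec.read_length
    builder = _BamBuilder(header, L, rng)

    barcodes = [f"BC{i:04d}" for i in range(spec.n_cells)]
    n_pos = int(round(spec.fraction_positive * spec.n_cells))
    positives = sorted(rng.choice(barcodes, size=n_pos, replace=False)) if n_pos else []
    single_cell = spec.n_cells > 0

    def any_barcode():
        return barcodes[rng.integers(0, len(barcodes))] if single_cell else None

    def positive_barcode():
        return positives[rng.integers(0, len(positives))] if single_cell else None

    def frag():
        return _clipped_normal(rng, spec.fragment_mean, spec.fragment_sd, 2 * L + 20, 2 * spec.fragment_mean)

    # Background: uniform concordant pairs per chromosome.
    for chrom, clen in lengths.items():
        n_pairs = int(round(spec.background_depth * clen / (2 * L)))
        for i in range(n_pairs):
            f = frag()
            p = int(rng.integers(0, clen - f))
            builder.add_pair(
                f"bg_{chrom}_{i}",
                (chrom, p, f"{L}M", False),
                (chrom, p + f - L, f"{L}M", True),
                proper=True,
                barcode=any_barcode(),
            )

    truth_junctions = []
    for ci, circle in enumerate(spec.circles):
        # Extra concordant pairs inside each segment up to the circle's depth.
        extra_depth = (circle.copy_multiplier - 1.0) * spec.background_depth
        if extra_depth > 0:
            for si, seg in enumerate(circle.segments):
                n_pairs = int(round(extra_depth * seg.length / (2 * L)))
                for i in range(n_pairs):
                    f = min(frag(), seg.length)
                    p = int(rng.integers(seg.start, max(seg.start + 1, seg.end - f)))
                    builder.add_pair(
                        f"amp_{ci}_{si}_{i}",
                        (seg.chrom, p, f"{L}M", False),
                        (seg.chrom, p + f - L, f"{L}M", True),
                        proper=True,
                        barcode=positive_barcode(),
                    )

        for ji, (exiting, entering) in enumerate(circle.junctions):
            bp_a, bp_b = exiting.exit_point, entering.entry_point
            # Positive cells take junction reads round-robin so every
            # positive barcode supports every junction at least once.
            rr = 0

            def junction_barcode():
                nonlocal rr
                if not single_cell:
                    return None
                bc = positives[rr % len(positives)]
                rr += 1
                return bc

            # Discordant-only pairs: the junction falls between the mates.
            for i in range(circle.n_discordant_per_junction):
                f = frag()
                u = int(rng.integers(1, max(2, f - 2 * L)))
                v = (f - 2 * L) - u
                builder.add_pair(
                    f"disc_{ci}_{ji}_{i}",
                    _mate_in_exiting(exiting, u, L),
                    _mate_in_entering(entering, v, L),
                    proper=False,
                    barcode=junction_barcode(),
                )
            # Split reads: the junction falls inside one read; its mate
            # maps past the junction in the entering segment, so the
            # pair is also discordant on the reference.
            for i in range(circle.n_split_per_junction):
                k = int(rng.integers(30, L - 29))
                f = frag()
                bc = junction_barcode()
                part_a, part_b = _junction_parts(exiting, entering, k, L)
                name = f"split_{ci}_{ji}_{i}"
                mate = _mate_in_entering(entering, f - L - k, L)
                primary, mate_rec = builder.add_pair(name, part_a, mate, proper=False, barcode=bc)
                supp = builder.add_single(name, part_b, supplementary=True, barcode=bc)
                supp.is_read1 = True
                supp.next_reference_id = mate_rec.reference_id
                supp.next_reference_start = mate_rec.reference_start
                supp.mate_is_reverse = mate_rec.is_reverse
                sa_of = lambda side: f"{side[0]},{side[1] + 1},{'-' if side[3] else '+'},{side[2]},60,0;"
                primary.set_tag("SA", sa_of(part_b), "Z")
                supp.set_tag("SA", sa_of(part_a), "Z")

            truth_junctions.append(
                {
                    "circle": ci,
                    "chrom_a": exiting.chrom,
                    "pos_a": bp_a,
                    "chrom_b": entering.chrom,
                    "pos_b": bp_b,
                    "n_split": circle.n_split_per_junction,
                    "n_discordant_pairs": circle.n_discordant_per_junction
                    + circle.n_split_per_junction,
                    "amplified": circle.copy_multiplier > 1.0,
                }
            )

    unsorted = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as fh:
        for rec in builder.records:
            fh.write(rec)
    pysam.sort("-o", str(out_bam), str(unsorted))
    unsorted.unlink()
    pysam.index(str(out_bam))

    genome_length = sum(lengths.values())
    truth = {
        "reference_lengths": lengths,
        "circles": [
            {
                "copy_multiplier": c.copy_multiplier,
                "depth": c.copy_multiplier * spec.background_depth,
                "segments": [
                    [s.chrom, s.start, s.end, s.orientation] for s in c.segments
                ],
            }
            for c in spec.circles
        ],
        "junctions": truth_junctions,
        "background_depth": spec.background_depth,
        "n_records": len(builder.records),
        "total_aligned_bases": builder.total_aligned_bases,
        "genome_length": genome_length,
        "exact_mean_depth": builder.total_aligned_bases / genome_length,
        "n_cells": spec.n_cells,
        "positive_barcodes": list(positives),
        "read_length": L,
        "seed": spec.seed,
    }
    if truth_json is not None:
        Path(truth_json).write_text(json.dumps(truth, indent=2))
    return out_bam, truth


def make_default_fixture(out_dir, seed: int = 17, n_cells: int = 0):
    """Reference + BAM + truth for the standard scenario, under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = make_reference(DEFAULT_REFERENCE_LENGTHS, out_dir / "reference.fa", seed)
    spec = default_fixture_spec(seed=seed, n_cells=n_cells)
    bam, truth = simulate_reads(spec, ref, out_dir / "reads.bam", out_dir / "truth.json")
    return ref, bam, truth
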