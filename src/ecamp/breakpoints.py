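"""Breakpoint pairs from split-read and discordant-pair evidence.

Split reads give exact junction coordinates: the clipped end of each
local alignment abuts the junction, so a leading soft/hard clip puts the
breakpoint at the alignment start and a trailing clip at the alignment
end. Discordant pairs only bracket a junction; each mate's start site is
expanded into an interval and pairs are merged by single linkage when
both sides overlap, yielding interval-valued breakpoint pairs.

All intervals are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from .extract import DiscordantPair, SplitAlignment, cigar_reference_length

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class BreakpointPair:
    """Two genomic loci joined by abnormal-read evidence.

    Split-only pairs have width-1 loci; discordant clusters carry the
    merged mate-start intervals. Loci are canonically ordered (chrom,
    start) so (a, b) and (b, a) are one object.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    evidence: str  # split | discordant | both
    support: int
    side_a: Optional[str] = None  # left_clip | right_clip (split evidence)
    side_b: Optional[str] = None
    orient_a: Optional[str] = None
    orient_b: Optional[str] = None
    split_pos_a: Optional[int] = None  # exact coordinates when evidence includes split
    split_pos_b: Optional[int] = None
    region_a_id: Optional[int] = None
    region_b_id: Optional[int] = None
    region_a_length: Optional[int] = None
    region_b_length: Optional[int] = None
    barcodes: set = field(default_factory=set)
    self_edge: bool = False

    @property
    def sort_key(self):
        return (self.chrom_a, self.start_a, self.chrom_b, self.start_b, self.evidence)

    def locus_a_contains(self, chrom, pos) -> bool:
        return chrom == self.chrom_a and self.start_a <= pos < self.end_a

    def locus_b_contains(self, chrom, pos) -> bool:
        return chrom == self.chrom_b and self.start_b <= pos < self.end_b


def _clip_lengths(cigar: str):
    ops = _CIGAR_RE.findall(cigar)
    if not ops:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    lead = trail = 0
    for n, op in ops:
        if op in "SH":
            lead += int(n)
        else:
            break
    for n, op in reversed(ops):
        if op in "SH":
            trail += int(n)
        else:
            break
    return lead, trail


def junction_side(cigar: str, start: int):
    """(breakpoint position, side) implied by the CIGAR's clipping.

    Returns None for an unclipped alignment. When both ends are clipped
    the longer clip wins (ties go to the leading clip).
    """
    lead, trail = _clip_lengths(cigar)
    if lead == 0 and trail == 0:
        return None
    if lead >= trail:
        return start, "left_clip"
    return start + cigar_reference_length(cigar), "right_clip"


def _orientation(strand: str, side: str) -> str:
    # Sign of the segment entering the junction: alignment strand XOR side.
    return "+" if (strand == "+") == (side == "right_clip") else "-"


def call_split_breakpoints(splits):
    """Aggregate split alignments into exact breakpoint pairs.

    Identical (chrom, pos, side, orientation) endpoint tuples are merged
    with summed support. Returns (pairs, stats) where stats counts
    alignments skipped for missing clips or ambiguous double clips.
    """
    counts = {}
    barcodes = {}
    stats = {"skipped_unclipped": 0, "double_clipped": 0}
    for aln in splits:
        try:
            primary = junction_side(aln.cigar, aln.start)
            supp = junction_side(aln.sa_cigar, aln.sa_pos)
        except ValueError:
            stats["skipped_unclipped"] += 1
            continue
        if primary is None or supp is None:
            stats["skipped_unclipped"] += 1
            continue
        lead_p, trail_p = _clip_lengths(aln.cigar)
        if lead_p and trail_p:
            stats["double_clipped"] += 1
        end1 = (aln.chrom, primary[0], primary[1], _orientation(aln.strand, primary[1]))
        end2 = (aln.sa_chrom, supp[0], supp[1], _orientation(aln.sa_strand, supp[1]))
        key = tuple(sorted((end1, end2), key=lambda e: (e[0], e[1])))
        counts[key] = counts.get(key, 0) + 1
        if aln.barcode is not None:
            barcodes.setdefault(key, set()).add(aln.barcode)
    pairs = []
    for (ea, eb), support in sorted(counts.items()):
        pairs.append(
            BreakpointPair(
                chrom_a=ea[0],
                start_a=ea[1],
                end_a=ea[1] + 1,
                chrom_b=eb[0],
                start_b=eb[1],
                end_b=eb[1] + 1,
                evidence="split",
                support=support,
                side_a=ea[2],
                side_b=eb[2],
                orient_a=ea[3],
                orient_b=eb[3],
                split_pos_a=ea[1],
                split_pos_b=eb[1],
                barcodes=barcodes.get((ea, eb), set()),
            )
        )
    return pairs, stats


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage_dual(items, a_interval, b_interval, group_key):
    """Connected components under simultaneous a- and b-side overlap.

    ``items`` is a sequence; the three accessors map an item to its
    half-open a interval, b interval and grouping key (items in
    different groups never merge). Returns a list of component index
    lists, deterministic for any input order.
    """
    order = sorted(
        range(len(items)),
        key=lambda i: (group_key(items[i]), a_interval(items[i]), b_interval(items[i])),
    )
    uf = _UnionFind(len(items))
    active = []
    current_group = object()
    for idx in order:
        item = items[idx]
        key = group_key(item)
        a_lo, a_hi = a_interval(item)
        b_lo, b_hi = b_interval(item)
        if key != current_group:
            active = []
            current_group = key
        active = [j for j in active if a_interval(items[j])[1] > a_lo]
        for j in active:
            jb_lo, jb_hi = b_interval(items[j])
            if jb_lo < b_hi and b_lo < jb_hi:
                uf.union(idx, j)
        active.append(idx)
    components = {}
    for i in range(len(items)):
        components.setdefault(uf.find(i), []).append(i)
    return sorted(components.values(), key=lambda member: min(member))


def cluster_discordant_pairs(discordants, cluster_halfwidth: int):
    """Merge discordant pairs into interval-valued breakpoint pairs.

    Each mate start site s seeds the interval [s - halfwidth,
    s + halfwidth]; two pairs join one cluster when their a-side
    intervals overlap AND their b-side intervals overlap (single
    linkage). Cluster intervals are unions of member intervals, support
    is the member count.
    """
    if not discordants:
        return []
    hw = cluster_halfwidth

    def a_iv(p):
        return (p.start_a - hw, p.start_a + hw + 1)

    def b_iv(p):
        return (p.start_b - hw, p.start_b + hw + 1)

    def key(p):
        return (p.chrom_a, p.chrom_b)

    clusters = []
    for members in _single_linkage_dual(discordants, a_iv, b_iv, key):
        ps = [discordants[i] for i in members]
        barcodes = {p.barcode for p in ps if p.barcode is not None}
        clusters.append(
            BreakpointPair(
                chrom_a=ps[0].chrom_a,
                start_a=min(a_iv(p)[0] for p in ps),
                end_a=max(a_iv(p)[1] for p in ps),
                chrom_b=ps[0].chrom_b,
                start_b=min(b_iv(p)[0] for p in ps),
                end_b=max(b_iv(p)[1] for p in ps),
                evidence="discordant",
                support=len(ps),
                barcodes=barcodes,
            )
        )
    clusters.sort(key=lambda c: c.sort_key)
    return clusters


def merge_neighboring_split_pairs(pairs, merge_range: int):
    """Merge split breakpoint pairs within ``merge_range`` bp on both sides.

    Single linkage; the representative coordinates are those of the
    highest-support member (ties: smallest coordinates); support sums.
    """
    if not pairs:
        return []
    # half-width intervals: two points overlap iff they are <= merge_range apart
    hw = merge_range // 2

    def a_iv(p):
        return (p.start_a - hw, p.start_a + hw + 1)

    def b_iv(p):
        return (p.start_b - hw, p.start_b + hw + 1)

    def key(p):
        return (p.chrom_a, p.chrom_b)

    merged = []
    for members in _single_linkage_dual(pairs, a_iv, b_iv, key):
        ps = [pairs[i] for i in members]
        rep = max(ps, key=lambda p: (p.support, -p.start_a, -p.start_b))
        out = replace(
            rep,
            support=sum(p.support for p in ps),
            barcodes=set().union(*(p.barcodes for p in ps)),
        )
        merged.append(out)
    merged.sort(key=lambda c: c.sort_key)
    return merged


def combine_split_and_discordant(split_pairs, clusters):
    """Fold exact split pairs into discordant clusters that contain them.

    A split pair whose two points fall inside a cluster's two intervals
    becomes part of that cluster (evidence "both", summed support, exact
    coordinates retained in split_pos_a/b). Unmatched split pairs pass
    through unchanged.
    """
    result = [replace(c) for c in clusters]
    for sp in split_pairs:
        host = None
        for c in result:
            if (
                c.locus_a_contains(sp.chrom_a, sp.start_a)
                and c.locus_b_contains(sp.chrom_b, sp.start_b)
            ) or (
                c.locus_a_contains(sp.chrom_b, sp.start_b)
                and c.locus_b_contains(sp.chrom_a, sp.start_a)
            ):
                host = c
                break
        if host is None:
            result.append(replace(sp))
        else:
            host.evidence = "both"
            host.support += sp.support
            host.barcodes = host.barcodes | sp.barcodes
            host.split_pos_a = sp.start_a
            host.split_pos_b = sp.start_b
            host.side_a, host.side_b = sp.side_a, sp.side_b
            host.orient_a, host.orient_b = sp.orient_a, sp.orient_b
    result.sort(key=lambda c: c.sort_key)
    return result


_TSV_COLUMNS = [
    "chrom_a",
    "start_a",
    "end_a",
    "chrom_b",
    "start_b",
    "end_b",
    "evidence",
    "support",
    "region_a_id",
    "region_b_id",
    "region_a_length",
    "region_b_length",
]


def write_breakpoint_file(pairs, path):
    """Deterministic TSV dump of breakpoint pairs (canonical sort order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for p in sorted(pairs, key=lambda p: p.sort_key):
            row = [
                p.chrom_a,
                p.start_a,
                p.end_a,
                p.chrom_b,
                p.start_b,
                p.end_b,
                p.evidence,
                p.support,
                p.region_a_id if p.region_a_id is not None else ".",
                p.region_b_id if p.region_b_id is not None else ".",
                p.region_a_length if p.region_a_length is not None else ".",
                p.region_b_length if p.region_b_length is not None else ".",
            ]
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


def read_breakpoint_file(path):
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"unexpected breakpoint file header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            opt = lambda v: None if v == "." else int(v)
            pairs.append(
                BreakpointPair(
                    chrom_a=f[0],
                    start_a=int(f[1]),
                    end_a=int(f[2]),
                    chrom_b=f[3],
                    start_b=int(f[4]),
                    end_b=int(f[5]),
                    evidence=f[6],
                    support=int(f[7]),
                    region_a_id=opt(f[8]),
                    region_b_id=opt(f[9]),
                    region_a_length=opt(f[10]),
                    region_b_length=opt(f[11]),
                )
            )
    return pairs
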