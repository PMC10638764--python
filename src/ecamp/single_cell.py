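"""Cell-barcode attribution of breakpoint support in single-cell mode.

Detection runs on the pooled reads exactly as in bulk mode; barcode
attribution is a post-hoc projection. A barcoded abnormal read supports
a breakpoint pair when (split read) its two junction coordinates fall
inside the pair's two loci, or (discordant pair) both mate start sites
do. Match intervals are padded by the breakpoint merge range, so exact
split coordinates still match pairs whose representative position
shifted during neighbor merging. Barcodes propagate from pairs to the
regions and co-amplified components they connect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Set

from .breakpoints import junction_side


@dataclass
class CellAssignment:
    barcode: str
    pair_ids: Set[int] = field(default_factory=set)
    region_ids: Set[int] = field(default_factory=set)
    component_ids: Set[int] = field(default_factory=set)
    n_supporting_reads: int = 0


class _PairMatcher:
    def __init__(self, pairs, pad: int):
        self._pairs = []
        for pid, p in enumerate(pairs, start=1):
            a = (p.chrom_a, p.start_a - pad, p.end_a + pad)
            b = (p.chrom_b, p.start_b - pad, p.end_b + pad)
            self._pairs.append((pid, p, a, b))

    @staticmethod
    def _inside(locus, chrom, pos):
        return locus[0] == chrom and locus[1] <= pos < locus[2]

    def match(self, chrom1, pos1, chrom2, pos2):
        for pid, pair, a, b in self._pairs:
            if (self._inside(a, chrom1, pos1) and self._inside(b, chrom2, pos2)) or (
                self._inside(a, chrom2, pos2) and self._inside(b, chrom1, pos1)
            ):
                yield pid, pair


def assign_barcodes(
    splits,
    discordants,
    pairs,
    regions,
    components,
    merge_range: int = 1000,
    min_reads_per_pair: int = 1,
):
    """Attribute barcodes to the pairs/regions/components they support.

    Returns (assignments, stats); assignments are sorted by barcode and
    only contain barcodes with at least one supporting read after the
    per-(barcode, pair) floor ``min_reads_per_pair`` is applied.
    """
    matcher = _PairMatcher(pairs, merge_range)
    region_by_id = {r.id: r for r in regions}
    component_of: Dict[int, int] = {}
    for comp in components:
        for node in comp.nodes:
            component_of[node] = comp.id

    read_counts: Dict[tuple, int] = {}
    stats = {"missing_barcode": 0, "matched_reads": 0, "unmatched_reads": 0}

    def record(barcode, chrom1, pos1, chrom2, pos2):
        if barcode is None:
            stats["missing_barcode"] += 1
            return
        matched = False
        for pid, _pair in matcher.match(chrom1, pos1, chrom2, pos2):
            read_counts[(barcode, pid)] = read_counts.get((barcode, pid), 0) + 1
            matched = True
        stats["matched_reads" if matched else "unmatched_reads"] += 1

    for aln in splits:
        primary = junction_side(aln.cigar, aln.start)
        supp = junction_side(aln.sa_cigar, aln.sa_pos)
        if primary is None or supp is None:
            continue
        record(aln.barcode, aln.chrom, primary[0], aln.sa_chrom, supp[0])

    for dp in discordants:
        record(dp.barcode, dp.chrom_a, dp.start_a, dp.chrom_b, dp.start_b)

    cells: Dict[str, CellAssignment] = {}
    pair_list = list(pairs)
    for (barcode, pid), count in sorted(read_counts.items()):
        if count < min_reads_per_pair:
            continue
        cell = cells.setdefault(barcode, CellAssignment(barcode))
        cell.pair_ids.add(pid)
        cell.n_supporting_reads += count
        pair = pair_list[pid - 1]
        for rid in (pair.region_a_id, pair.region_b_id):
            if rid is not None and rid in region_by_id:
                cell.region_ids.add(rid)
                cell.component_ids.add(component_of[rid])
    assignments = [cells[bc] for bc in sorted(cells)]
    if not assignments and (splits or discordants):
        total_abnormal = len(splits) + len(discordants)
        if stats["missing_barcode"] == total_abnormal:
            raise ValueError(
                "no abnormal read carried a cell barcode; check the barcode "
                "tag name (default CB) against your BAM"
            )
    return assignments, stats


def component_barcodes(assignments) -> Dict[int, Set[str]]:
    """Barcode set per component (union over member pairs' supporters)."""
    out: Dict[int, Set[str]] = {}
    for cell in assignments:
        for cid in cell.component_ids:
            out.setdefault(cid, set()).add(cell.barcode)
    return out


def write_cell_barcodes(assignments, path):
    with open(path, "w") as fh:
        fh.write("barcode\tcomponent_id\tregion_ids\tpair_ids\tn_supporting_reads\n")
        for cell in assignments:
            comps = ",".join(map(str, sorted(cell.component_ids))) or "."
            fh.write(
                f"{cell.barcode}\t{comps}\t"
                f"{','.join(map(str, sorted(cell.region_ids))) or '.'}\t"
                f"{','.join(map(str, sorted(cell.pair_ids))) or '.'}\t"
                f"{cell.n_supporting_reads}\n"
            )
    return path
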