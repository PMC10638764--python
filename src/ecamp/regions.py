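"""Amplified-region calling: grow coverage windows out from breakpoint seeds.

Starting at the midpoint of a breakpoint locus, windows of
``window_size`` bp are checked upstream and downstream. A window is
accepted while its own mean depth reaches the amplification threshold
covt; windows below covt are tolerated (up to ``max_dip_windows``
consecutively) while the running mean of the region including them
stays at or above covt, which bridges local dips without letting a
long-finished amplicon drag the extension onward. Trailing tolerated
windows are trimmed, so a region always ends on an above-threshold
window. Regions shorter than ``min_region_length`` are discarded along
with the breakpoint-pair sides they would anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import pandas as pd

from .coverage import CoverageProfile
from .params import DetectionParameters


@dataclass
class AmplifiedRegion:
    """Contiguous interval whose mean depth exceeds covt."""

    id: int
    chrom: str
    start: int  # 0-based half-open
    end: int
    mean_depth: float
    genes: List[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start < end and start < self.end


def grow_region(
    chrom: str,
    seed_start: int,
    seed_end: int,
    coverage: CoverageProfile,
    window: int,
    covt: float,
    max_dip_windows: int = 2,
) -> Optional[Tuple[int, int]]:
    """Extend an amplified interval outward from a seed locus midpoint.

    Returns the half-open interval, or None when even the initial
    window centered on the midpoint is below covt. The interval is
    clipped at chromosome bounds.
    """
    if chrom not in coverage.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom}")
    clen = coverage.chrom_lengths[chrom]
    mid = (seed_start + seed_end) // 2
    if not (0 <= mid < clen):
        raise ValueError(f"seed midpoint {chrom}:{mid} outside chromosome (len {clen})")

    start = max(0, min(mid - window // 2, max(0, clen - window)))
    end = min(clen, start + window)
    initial_mean = coverage.mean_depth(chrom, start, end)
    if initial_mean < covt:
        return None
    initial_bases = initial_mean * (end - start)

    def extend(edge: int, step: int) -> int:
        """Sweep one direction; returns the final (trimmed) edge."""
        cum = initial_bases
        length = end - start
        good_edge = edge
        dip_run = 0
        while True:
            if step > 0:
                nxt_lo, nxt_hi = edge, min(edge + window, clen)
            else:
                nxt_lo, nxt_hi = max(edge - window, 0), edge
            if nxt_hi <= nxt_lo:
                break
            span = nxt_hi - nxt_lo
            win_mean = coverage.mean_depth(chrom, nxt_lo, nxt_hi)
            cum += win_mean * span
            length += span
            edge = nxt_hi if step > 0 else nxt_lo
            if win_mean >= covt:
                dip_run = 0
                good_edge = edge
            elif cum / length >= covt and dip_run < max_dip_windows:
                dip_run += 1
            else:
                break
            if edge in (0, clen):
                break
        return good_edge

    new_end = extend(end, +1)
    new_start = extend(start, -1)
    return new_start, new_end


def call_regions(pairs, coverage: CoverageProfile, params: DetectionParameters):
    """Grow, deduplicate, filter and number amplified regions; assign ids.

    Two phases: (1) every breakpoint-pair locus (discordant clusters
    first, then split-only pairs) seeds a region grow; overlapping grown
    intervals are unified. (2) each pair side is assigned the retained
    region containing its midpoint; sides without a region stay
    unassigned, pairs with both sides unassigned are dropped, and pairs
    connecting the same two regions merge with summed support.

    Returns (regions, updated_pairs).
    """
    covt = coverage.covt
    window = params.window_size

    def seeds_of(pair):
        yield (pair.chrom_a, pair.start_a, pair.end_a)
        yield (pair.chrom_b, pair.start_b, pair.end_b)

    ordered = sorted(
        pairs, key=lambda p: (p.evidence == "split", p.sort_key)
    )  # interval-valued cluster pairs first

    grown: List[Tuple[str, int, int]] = []
    for pair in ordered:
        for chrom, lo, hi in seeds_of(pair):
            mid = (lo + hi) // 2
            if any(c == chrom and s <= mid < e for c, s, e in grown):
                continue
            interval = grow_region(
                chrom, lo, hi, coverage, window, covt, params.max_dip_windows
            )
            if interval is None:
                continue
            s, e = interval
            # Unify with any overlapping previously grown intervals.
            keep = []
            for c, gs, ge in grown:
                if c == chrom and gs < e and s < ge:
                    s, e = min(s, gs), max(e, ge)
                else:
                    keep.append((c, gs, ge))
            keep.append((chrom, s, e))
            grown = keep

    retained = [
        (c, s, e) for c, s, e in grown if e - s >= params.min_region_length
    ]
    retained.sort()
    regions = [
        AmplifiedRegion(
            id=i + 1,
            chrom=c,
            start=s,
            end=e,
            mean_depth=coverage.mean_depth(c, s, e),
        )
        for i, (c, s, e) in enumerate(retained)
    ]

    def region_for(chrom, lo, hi):
        # Region boundaries are window-quantized while breakpoint loci are
        # base-precise, so fall back from midpoint containment to the
        # best-overlapping region within one window of the locus.
        mid = (lo + hi) // 2
        for r in regions:
            if r.contains(chrom, mid):
                return r
        best, best_ov = None, 0
        for r in regions:
            ov = min(r.end, hi + window) - max(r.start, lo - window)
            if r.chrom == chrom and ov > best_ov:
                best, best_ov = r, ov
        return best

    merged = {}
    for pair in ordered:
        ra = region_for(pair.chrom_a, pair.start_a, pair.end_a)
        rb = region_for(pair.chrom_b, pair.start_b, pair.end_b)
        if ra is None and rb is None:
            continue
        p = replace(
            pair,
            region_a_id=ra.id if ra else None,
            region_a_length=ra.length if ra else None,
            region_b_id=rb.id if rb else None,
            region_b_length=rb.length if rb else None,
            self_edge=(ra is not None and ra is rb),
            barcodes=set(pair.barcodes),
        )
        if p.region_a_id and p.region_b_id:
            key = tuple(sorted((p.region_a_id, p.region_b_id)))
        else:  # one-sided pairs stay distinct per locus
            key = (p.region_a_id, p.region_b_id, p.sort_key)
        if key in merged:
            host = merged[key]
            host.support += p.support
            host.barcodes |= p.barcodes
            if host.evidence != p.evidence:
                host.evidence = "both"
        else:
            merged[key] = p
    updated = sorted(merged.values(), key=lambda p: p.sort_key)
    return regions, updated


REGION_COLUMNS = ["region_id", "chrom", "start", "end", "length", "mean_depth", "genes"]


def write_regions_table(regions, path):
    """regions.tsv with half-open coordinates, so length == end - start."""
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                f"{r.id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.length}\t"
                f"{r.mean_depth:.3f}\t{','.join(r.genes)}\n"
            )
    return path


def write_regions_bed(regions, path):
    with open(path, "w") as fh:
        for r in regions:
            score = min(1000, round(r.mean_depth))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tregion_{r.id}\t{score}\t.\n"
            )
    return path


def load_regions_table(path) -> pd.DataFrame:
    """Read a regions table and verify its coordinate arithmetic.

    Raises ValueError if any row violates length == end - start.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing = {"chrom", "start", "end", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"regions table {path} lacks columns {sorted(missing)}")
    bad = df[df["end"] - df["start"] != df["length"]]
    if len(bad):
        raise ValueError(
            f"{len(bad)} rows in {path} violate length == end - start"
        )
    return df
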