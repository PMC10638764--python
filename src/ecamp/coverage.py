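"""Per-base depth access and genome-wide mean estimation.

Depth is counted from the original BAM: every base a primary,
non-duplicate alignment spans on the reference counts once. The
amplification threshold covt is a configurable multiple of the
genome-wide mean depth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam


def _usable(rec) -> bool:
    return not (
        rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate
    )


def exact_genome_mean(bam_path) -> float:
    """Total aligned bases over total genome length (full pass)."""
    total = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        genome = sum(bam.lengths)
        if genome == 0:
            raise ValueError(f"cannot estimate depth: empty header in {bam_path}")
        for rec in bam.fetch(until_eof=True):
            if _usable(rec):
                total += rec.reference_length or 0
    if total == 0:
        raise ValueError(f"cannot estimate depth: no aligned reads in {bam_path}")
    return total / genome


def estimate_genome_mean(
    bam_path, seed: int, n_samples: int = 2000, window: int = 1000
) -> float:
    """Mean per-base depth from random windows.

    Windows are drawn uniformly over the genome (chromosomes weighted by
    length); windows with zero reads contribute zero. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        lengths = np.array(bam.lengths, dtype=float)
        names = bam.references
        if lengths.sum() == 0:
            raise ValueError(f"cannot estimate depth: empty header in {bam_path}")
        probs = lengths / lengths.sum()
        total = 0.0
        any_reads = bam.mapped > 0
        if not any_reads:
            raise ValueError(f"cannot estimate depth: no aligned reads in {bam_path}")
        for _ in range(n_samples):
            ci = int(rng.choice(len(names), p=probs))
            clen = int(lengths[ci])
            w = min(window, clen)
            start = int(rng.integers(0, max(1, clen - w + 1)))
            end = start + w
            covered = 0
            for rec in bam.fetch(names[ci], start, end):
                if _usable(rec):
                    covered += min(end, rec.reference_end) - max(start, rec.reference_start)
            total += covered / w
    return total / n_samples


class CoverageProfile:
    """Windowed mean-depth accessor over an indexed BAM.

    Carries the genome-wide mean and the derived amplification
    threshold ``covt = covt_multiplier * genome_mean``. Window queries
    are cached, so repeated seeds over the same amplicon are cheap.
    """

    def __init__(self, bam_path, genome_mean: float, covt_multiplier: float):
        self.bam_path = Path(bam_path)
        self._bam = pysam.AlignmentFile(str(self.bam_path), "rb")
        self.chrom_lengths = dict(zip(self._bam.references, self._bam.lengths))
        if genome_mean <= 0:
            raise ValueError("genome_mean must be positive")
        self.genome_mean = genome_mean
        self.covt = covt_multiplier * genome_mean
        self._cache = {}

    @classmethod
    def from_bam(
        cls,
        bam_path,
        covt_multiplier: float,
        seed: int = 17,
        n_samples: int = 2000,
        full_pass: bool = False,
    ) -> "CoverageProfile":
        mean = (
            exact_genome_mean(bam_path)
            if full_pass
            else estimate_genome_mean(bam_path, seed=seed, n_samples=n_samples)
        )
        return cls(bam_path, mean, covt_multiplier)

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom}")
        clen = self.chrom_lengths[chrom]
        start, end = max(0, start), min(end, clen)
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        key = (chrom, start, end)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        covered = 0
        for rec in self._bam.fetch(chrom, start, end):
            if _usable(rec):
                covered += min(end, rec.reference_end) - max(start, rec.reference_start)
        value = covered / (end - start)
        self._cache[key] = value
        return value

    def close(self):
        self._bam.close()
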