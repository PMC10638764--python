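"""Run parameters shared across pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


VALID_MODES = ("from_bam", "from_abnormal")


@dataclass
class DetectionParameters:
    """Tunable knobs of the detection pipeline.

    All length-like fields are in base pairs.

    Parameters
    ----------
    fragment_length_threshold
        Reference span above which a same-chromosome read pair is called
        discordant. Recommended default 1000 for standard short-fragment
        ATAC libraries.
    cluster_halfwidth
        Half-width of the interval built around each discordant mate's
        alignment start site before single-linkage merging.
    window_size
        Step of the sliding window used to extend amplified regions
        outward from breakpoint seeds.
    merge_range
        Distance (per side) within which neighboring split-read
        breakpoints are merged into one breakpoint pair.
    min_region_length
        Amplified regions shorter than this are discarded together with
        the breakpoint-pair sides they would anchor.
    covt_multiplier
        The amplification depth threshold covt is this multiple of the
        genome-wide mean depth.
    max_dip_windows
        Number of consecutive below-covt windows tolerated during region
        extension while the running region mean stays above covt.
        Trailing tolerated windows are trimmed from the final region.
    mapq_min
        Reads below this mapping quality (or flagged duplicate /
        secondary / supplementary) never enter the abnormal-read streams.
    barcode_tag
        BAM tag holding the cell barcode in single-cell mode.
    depth_samples
        Number of random windows drawn when estimating the genome-wide
        mean depth (ignored in full-pass mode).
    """

    fragment_length_threshold: int = 1000
    cluster_halfwidth: int = 500
    window_size: int = 1000
    merge_range: int = 1000
    min_region_length: int = 3000
    covt_multiplier: float = 3.0
    max_dip_windows: int = 2
    mapq_min: int = 1
    barcode_tag: str = "CB"
    threads: int = 1
    mode: str = "from_bam"
    single_cell: bool = False
    depth_samples: int = 2000
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "fragment_length_threshold",
            "cluster_halfwidth",
            "window_size",
            "merge_range",
            "min_region_length",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.covt_multiplier <= 0:
            raise ValueError("covt_multiplier must be > 0")
        if self.min_region_length < self.window_size:
            raise ValueError("min_region_length must be >= window_size")
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.max_dip_windows < 0:
            raise ValueError("max_dip_windows must be >= 0")

    def replace(self, **kwargs) -> "DetectionParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
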