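"""End-to-end orchestration: BAM -> breakpoints -> regions -> graph ->
annotation -> (single-cell barcodes), with a run manifest.

Per-chromosome read classification can be distributed over threads; the
per-chromosome results are merged in header order, so every text output
is independent of the thread count.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pysam

from . import __version__
from .annotate import annotate_regions, load_gtf
from .breakpoints import (
    call_split_breakpoints,
    cluster_discordant_pairs,
    combine_split_and_discordant,
    merge_neighboring_split_pairs,
    write_breakpoint_file,
)
from .coverage import CoverageProfile
from .extract import classify_reads, load_abnormal_bams, write_abnormal_bams
from .graph import build_graph, export_graph, find_components_and_cycles
from .params import DetectionParameters
from .regions import call_regions, write_regions_bed, write_regions_table
from .single_cell import assign_barcodes, write_cell_barcodes

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    out_dir: Path
    params: DetectionParameters
    splits: list = field(default_factory=list)
    discordants: list = field(default_factory=list)
    split_pairs: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    graph: object = None
    components: list = field(default_factory=list)
    cell_assignments: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _classify_parallel(bam_path, params: DetectionParameters):
    """Classify per chromosome across threads; merge in header order."""
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        contigs = list(bam.references)
    if params.threads <= 1:
        return classify_reads(bam_path, params)
    with ThreadPoolExecutor(max_workers=params.threads) as pool:
        futures = [
            pool.submit(classify_reads, bam_path, params, contig) for contig in contigs
        ]
        results = [f.result() for f in futures]
    splits, discordants = [], []
    summary = {}
    for s, d, summ in results:
        splits.extend(s)
        discordants.extend(d)
        for k, v in summ.items():
            summary[k] = summary.get(k, 0) + v
    return splits, discordants, summary


def run_pipeline(
    bam: str,
    out_dir: str,
    params: Optional[DetectionParameters] = None,
    gtf: Optional[str] = None,
    split_bam: Optional[str] = None,
    discordant_bam: Optional[str] = None,
    full_pass_depth: bool = False,
    make_images: bool = True,
) -> PipelineResult:
    """Run the full detection pipeline; all outputs land under out_dir.

    ``params.mode`` selects the entry point: ``from_bam`` extracts the
    abnormal reads itself, ``from_abnormal`` consumes pre-existing
    split/discordant BAMs (the original BAM is still required for the
    coverage model). The manifest is written even on failure.
    """
    params = params or DetectionParameters()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out_dir, params=params)
    manifest = {
        "tool": "ecamp",
        "version": __version__,
        "inputs": {
            "bam": str(bam),
            "gtf": str(gtf) if gtf else None,
            "split_bam": str(split_bam) if split_bam else None,
            "discordant_bam": str(discordant_bam) if discordant_bam else None,
        },
        "parameters": params.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "running",
    }
    result.manifest = manifest
    t_start = time.time()

    def stage(name):
        logger.info("=== stage: %s ===", name)
        return time.time()

    try:
        t = stage("abnormal read extraction")
        if params.mode == "from_abnormal":
            if not (split_bam and discordant_bam):
                raise ValueError(
                    "from_abnormal mode requires --split-bam and --discordant-bam"
                )
            splits, discordants = load_abnormal_bams(split_bam, discordant_bam, params)
            summary = {
                "split_reads": len(splits),
                "discordant_pairs": len(discordants),
            }
        else:
            sp_bam, dc_bam, summary = write_abnormal_bams(bam, out_dir, params)
            manifest["outputs_abnormal"] = [str(sp_bam), str(dc_bam)]
            splits, discordants, _ = _classify_parallel(bam, params)
        result.splits, result.discordants = splits, discordants
        manifest["stages"]["extraction"] = {
            "seconds": round(time.time() - t, 2),
            "split_reads": summary.get("split_reads", len(splits)),
            "discordant_pairs": summary.get("discordant_pairs", len(discordants)),
        }

        t = stage("breakpoint building")
        split_pairs, split_stats = call_split_breakpoints(splits)
        split_pairs = merge_neighboring_split_pairs(split_pairs, params.merge_range)
        clusters = cluster_discordant_pairs(discordants, params.cluster_halfwidth)
        pairs = combine_split_and_discordant(split_pairs, clusters)
        result.split_pairs, result.clusters = split_pairs, clusters
        write_breakpoint_file(split_pairs, out_dir / "breakpoints.split.tsv")
        write_breakpoint_file(clusters, out_dir / "breakpoints.discordant.tsv")
        manifest["stages"]["breakpoints"] = {
            "seconds": round(time.time() - t, 2),
            "split_pairs": len(split_pairs),
            "discordant_clusters": len(clusters),
            "combined_pairs": len(pairs),
            **split_stats,
        }

        t = stage("coverage model and region growth")
        coverage = CoverageProfile.from_bam(
            bam,
            covt_multiplier=params.covt_multiplier,
            seed=params.seed,
            n_samples=params.depth_samples,
            full_pass=full_pass_depth,
        )
        regions, pairs = call_regions(pairs, coverage, params)
        result.pairs, result.regions = pairs, regions
        manifest["stages"]["regions"] = {
            "seconds": round(time.time() - t, 2),
            "genome_mean_depth": round(coverage.genome_mean, 4),
            "covt": round(coverage.covt, 4),
            "regions": len(regions),
            "pairs_retained": len(pairs),
        }

        t = stage("annotation")
        if gtf:
            index = load_gtf(gtf)
            annotate_regions(regions, index)
            manifest["stages"]["annotation"] = {
                "seconds": round(time.time() - t, 2),
                "genes_indexed": len(index),
            }
        write_regions_table(regions, out_dir / "regions.tsv")
        write_regions_bed(regions, out_dir / "regions.bed")
        write_breakpoint_file(pairs, out_dir / "breakpoints.tsv")

        t = stage("co-amplification graph")
        g = build_graph(regions, pairs)
        components = find_components_and_cycles(g)
        export_graph(g, components, out_dir, make_images=make_images)
        result.graph, result.components = g, components
        manifest["stages"]["graph"] = {
            "seconds": round(time.time() - t, 2),
            "components": len(components),
            "cycles": sum(len(c.cycles) for c in components),
        }

        if params.single_cell:
            t = stage("cell barcode attribution")
            assignments, sc_stats = assign_barcodes(
                splits,
                discordants,
                pairs,
                regions,
                components,
                merge_range=params.merge_range,
            )
            result.cell_assignments = assignments
            write_cell_barcodes(assignments, out_dir / "cell_barcodes.tsv")
            manifest["stages"]["single_cell"] = {
                "seconds": round(time.time() - t, 2),
                "barcodes": len(assignments),
                **sc_stats,
            }
        coverage.close()
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs", manifest["elapsed_seconds"])
    return result
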