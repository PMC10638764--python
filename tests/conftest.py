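"""Shared fixtures: simulated BAMs and one pipeline run per scenario."""

from pathlib import Path

import pysam
import pytest

from ecamp import DetectionParameters, run_pipeline
from ecamp.simulate import EcdnaSpec, make_default_fixture, make_reference, simulate_reads

SEED = 17

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def bulk_fixture(tmp_path_factory):
    """Default planted scenario, bulk mode: (reference, bam, truth)."""
    out = tmp_path_factory.mktemp("bulk_fixture")
    ref, bam, truth = make_default_fixture(out, seed=SEED, n_cells=0)
    return {"reference": ref, "bam": bam, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def sc_fixture(tmp_path_factory):
    """Same scenario with 100 cells, 20 of them carrying the amplicon."""
    out = tmp_path_factory.mktemp("sc_fixture")
    ref, bam, truth = make_default_fixture(out, seed=SEED, n_cells=100)
    return {"reference": ref, "bam": bam, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def uniform_fixture(tmp_path_factory):
    """Single 200 kb chromosome at a uniform 10x, no planted circles."""
    out = tmp_path_factory.mktemp("uniform_fixture")
    ref = make_reference({"chr1": 200_000}, out / "reference.fa", SEED)
    spec = EcdnaSpec(circles=[], background_depth=10.0, seed=SEED)
    bam, truth = simulate_reads(spec, ref, out / "reads.bam")
    return {"reference": ref, "bam": bam, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def bulk_result(bulk_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("bulk_run")
    return run_pipeline(
        str(bulk_fixture["bam"]), out, DetectionParameters(), make_images=False
    )


@pytest.fixture(scope="session")
def sc_result(sc_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("sc_run")
    return run_pipeline(
        str(sc_fixture["bam"]),
        out,
        DetectionParameters(single_cell=True),
        make_images=False,
    )


def build_bam(path, lengths, rows):
    """Write a small sorted+indexed BAM from row dicts.

    Row keys: name, chrom, pos, cigar (default 100M), reverse, mapq,
    paired, proper, mate=(chrom, pos, reverse) or None, tlen, tags,
    read1, secondary, supplementary, duplicate.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in lengths.items()],
        }
    )
    path = Path(path)
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as fh:
        for row in rows:
            rec = pysam.AlignedSegment(header)
            rec.query_name = row["name"]
            rec.reference_id = header.get_tid(row["chrom"])
            rec.reference_start = row["pos"]
            rec.cigarstring = row.get("cigar", "100M")
            rec.mapping_quality = row.get("mapq", 60)
            qlen = rec.infer_query_length() or 100
            rec.query_sequence = "A" * qlen
            rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            rec.is_reverse = row.get("reverse", False)
            rec.is_paired = row.get("paired", True)
            rec.is_proper_pair = row.get("proper", False)
            rec.is_secondary = row.get("secondary", False)
            rec.is_supplementary = row.get("supplementary", False)
            rec.is_duplicate = row.get("duplicate", False)
            if row.get("read1", True):
                rec.is_read1 = True
            else:
                rec.is_read2 = True
            mate = row.get("mate")
            if mate is not None:
                rec.next_reference_id = header.get_tid(mate[0])
                rec.next_reference_start = mate[1]
                rec.mate_is_reverse = mate[2] if len(mate) > 2 else False
                rec.mate_is_unmapped = False
            else:
                rec.mate_is_unmapped = rec.is_paired
            rec.template_length = row.get("tlen", 0)
            for tag, value in row.get("tags", {}).items():
                rec.set_tag(tag, value)
            fh.write(rec)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return path
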