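"""Coverage model and amplified-region growth/filtering."""

import pysam
import pytest

from ecamp import (
    DetectionParameters,
    call_regions,
    estimate_genome_mean,
    exact_genome_mean,
    grow_region,
    load_regions_table,
)
from ecamp.breakpoints import BreakpointPair
from ecamp.regions import write_regions_table
from conftest import build_bam


class FakeCoverage:
    """Piecewise-constant depth profile: plateaus over a flat background."""

    def __init__(self, chrom_lengths, plateaus, background=5.0, covt=None,
                 genome_mean=10.0):
        self.chrom_lengths = chrom_lengths
        self.plateaus = plateaus  # (chrom, start, end, depth)
        self.background = background
        self.genome_mean = genome_mean
        self.covt = covt

    def mean_depth(self, chrom, start, end):
        start, end = max(0, start), min(end, self.chrom_lengths[chrom])
        total = self.background * (end - start)
        for c, s, e, d in self.plateaus:
            if c == chrom:
                ov = min(end, e) - max(start, s)
                if ov > 0:
                    total += (d - self.background) * ov
        return total / (end - start)


CHR = {"chr1": 1_000_000}


class TestGrowRegion:
    def test_plateau_recovered_within_one_window(self):
        cov = FakeCoverage(CHR, [("chr1", 100_000, 400_000, 50.0)])
        lo, hi = grow_region("chr1", 250_000, 250_000, cov, 1000, 15.0)
        assert abs(lo - 100_000) <= 1000 and abs(hi - 400_000) <= 1000

    def test_background_seed_returns_none(self):
        cov = FakeCoverage(CHR, [])
        assert grow_region("chr1", 250_000, 250_000, cov, 1000, 15.0) is None

    def test_uniform_high_depth_spans_chromosome(self):
        cov = FakeCoverage(CHR, [("chr1", 0, 1_000_000, 50.0)])
        assert grow_region("chr1", 250_000, 250_000, cov, 1000, 15.0) == (0, 1_000_000)

    def test_single_dip_is_bridged(self):
        # 1 kb dip to 10x between two 50x plateaus; running mean stays high.
        cov = FakeCoverage(
            CHR,
            [("chr1", 100_000, 200_000, 50.0), ("chr1", 201_000, 300_000, 50.0),
             ("chr1", 200_000, 201_000, 10.0)],
        )
        lo, hi = grow_region("chr1", 150_000, 150_000, cov, 1000, 20.0)
        assert lo <= 101_000 and hi >= 299_000

    def test_trailing_dips_are_trimmed(self):
        cov = FakeCoverage(CHR, [("chr1", 100_000, 200_000, 50.0)])
        lo, hi = grow_region("chr1", 150_000, 150_000, cov, 1000, 20.0)
        # background after the plateau must not be carried by the high
        # running mean of the finished amplicon
        assert hi <= 201_000 and lo >= 99_000

    def test_anti_monotone_in_covt(self):
        cov = FakeCoverage(CHR, [("chr1", 100_000, 200_000, 50.0)])
        previous = None
        for covt in (10.0, 20.0, 40.0):
            lo, hi = grow_region("chr1", 150_000, 150_000, cov, 1000, covt)
            if previous is not None:
                assert lo >= previous[0] and hi <= previous[1]
            previous = (lo, hi)

    def test_reseeding_inside_region_is_stable(self):
        cov = FakeCoverage(CHR, [("chr1", 100_000, 200_000, 50.0)])
        reference = grow_region("chr1", 150_000, 150_000, cov, 1000, 20.0)
        for seed in (110_000, 160_000, 199_000):
            lo, hi = grow_region("chr1", seed, seed, cov, 1000, 20.0)
            assert abs(lo - reference[0]) <= 1000 and abs(hi - reference[1]) <= 1000

    def test_seed_outside_chromosome_raises(self):
        cov = FakeCoverage(CHR, [])
        with pytest.raises(ValueError, match="chr1"):
            grow_region("chr1", 2_000_000, 2_000_000, cov, 1000, 15.0)


def _cluster(c1, s1, c2, s2, hw=500, support=10, evidence="discordant"):
    return BreakpointPair(c1, s1 - hw, s1 + hw + 1, c2, s2 - hw, s2 + hw + 1,
                          evidence, support)


class TestCallRegions:
    def test_junction_between_two_plateaus(self):
        cov = FakeCoverage(
            {"chr1": 1_000_000, "chr2": 1_000_000},
            [("chr1", 100_000, 300_000, 50.0), ("chr2", 500_000, 700_000, 50.0)],
            covt=20.0,
        )
        pairs = [_cluster("chr1", 300_000, "chr2", 500_000)]
        regions, updated = call_regions(pairs, cov, DetectionParameters())
        assert len(regions) == 2
        (p,) = updated
        assert {p.region_a_id, p.region_b_id} == {1, 2}
        assert not p.self_edge

    def test_short_region_dropped_with_its_pair(self):
        # both breakpoints anchor a 2 kb plateau: below min_region_length
        # (covt set so that boundary windows straddling the plateau fail)
        cov = FakeCoverage(CHR, [("chr1", 100_000, 102_000, 100.0)], covt=80.0)
        pairs = [_cluster("chr1", 100_900, "chr1", 101_100)]
        regions, updated = call_regions(pairs, cov, DetectionParameters())
        assert regions == [] and updated == []

    def test_one_sided_pair_kept_unassigned(self):
        cov = FakeCoverage(
            CHR, [("chr1", 100_000, 300_000, 50.0)], covt=20.0
        )
        pairs = [_cluster("chr1", 200_000, "chr1", 800_000)]
        regions, updated = call_regions(pairs, cov, DetectionParameters())
        assert len(regions) == 1
        (p,) = updated
        assert p.region_a_id == 1 and p.region_b_id is None

    def test_pairs_sharing_regions_merge_with_summed_support(self):
        cov = FakeCoverage(
            {"chr1": 1_000_000, "chr2": 1_000_000},
            [("chr1", 100_000, 300_000, 50.0), ("chr2", 500_000, 700_000, 50.0)],
            covt=20.0,
        )
        pairs = [
            _cluster("chr1", 120_000, "chr2", 520_000, support=7),
            _cluster("chr1", 280_000, "chr2", 680_000, support=5),
        ]
        regions, updated = call_regions(pairs, cov, DetectionParameters())
        assert len(regions) == 2
        (p,) = updated
        assert p.support == 12

    def test_self_edge_flagged(self):
        cov = FakeCoverage(CHR, [("chr1", 100_000, 300_000, 50.0)], covt=20.0)
        pairs = [_cluster("chr1", 110_000, "chr1", 290_000)]
        regions, updated = call_regions(pairs, cov, DetectionParameters())
        assert len(regions) == 1
        assert updated[0].self_edge

    def test_region_invariants_on_fixture(self, bulk_result):
        covt = bulk_result.manifest["stages"]["regions"]["covt"]
        regions = bulk_result.regions
        for r in regions:
            assert r.mean_depth >= covt
            assert r.length >= 3000
            assert r.length == r.end - r.start
        for a in regions:
            for b in regions:
                if a.id != b.id:
                    assert not a.overlaps(b.chrom, b.start, b.end)


class TestGenomeMean:
    def test_uniform_fixture_sampled_within_5_percent(self, uniform_fixture):
        mean = estimate_genome_mean(uniform_fixture["bam"], seed=7, n_samples=500)
        assert mean == pytest.approx(10.0, rel=0.05)

    def test_full_pass_equals_closed_form(self, uniform_fixture):
        truth = uniform_fixture["truth"]
        mean = exact_genome_mean(uniform_fixture["bam"])
        assert mean == pytest.approx(
            truth["total_aligned_bases"] / truth["genome_length"], rel=1e-9
        )

    def test_sampling_is_deterministic_under_seed(self, uniform_fixture):
        a = estimate_genome_mean(uniform_fixture["bam"], seed=3, n_samples=100)
        b = estimate_genome_mean(uniform_fixture["bam"], seed=3, n_samples=100)
        assert a == b

    def test_empty_bam_raises(self, tmp_path):
        bam = build_bam(tmp_path / "e.bam", {"chr1": 10_000}, [])
        with pytest.raises(ValueError, match="cannot estimate depth"):
            exact_genome_mean(bam)
        with pytest.raises(ValueError, match="cannot estimate depth"):
            estimate_genome_mean(bam, seed=1, n_samples=10)


def test_regions_table_roundtrip_and_arithmetic(tmp_path, bulk_result):
    path = tmp_path / "regions.tsv"
    write_regions_table(bulk_result.regions, path)
    df = load_regions_table(path)
    assert len(df) == len(bulk_result.regions)
    assert (df["end"] - df["start"] == df["length"]).all()


def test_regions_table_rejects_bad_arithmetic(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("region_id\tchrom\tstart\tend\tlength\tmean_depth\tgenes\n"
                    "1\tchr1\t100\t200\t150\t10.0\t\n")
    with pytest.raises(ValueError, match="length == end - start"):
        load_regions_table(path)
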