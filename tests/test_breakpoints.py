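"""Breakpoint calling: CIGAR arithmetic, clustering, merging, round trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bruteforce_dual_clusters
from ecamp import (
    DetectionParameters,
    call_split_breakpoints,
    classify_reads,
    cluster_discordant_pairs,
    combine_split_and_discordant,
    merge_neighboring_split_pairs,
)
from ecamp.breakpoints import (
    BreakpointPair,
    junction_side,
    read_breakpoint_file,
    write_breakpoint_file,
)
from ecamp.extract import DiscordantPair, SplitAlignment


def _split(chrom, start, cigar, strand, sa_chrom, sa_pos, sa_cigar, sa_strand="+", name="r"):
    return SplitAlignment(
        read_name=name, chrom=chrom, start=start, end=None, strand=strand,
        cigar=cigar, sa_chrom=sa_chrom, sa_pos=sa_pos, sa_strand=sa_strand,
        sa_cigar=sa_cigar,
    )


def _dpair(name, c1, s1, c2, s2):
    return DiscordantPair.from_loci(name, (c1, s1, s1 + 100, "+"), (c2, s2, s2 + 100, "-"), span=0)


class TestJunctionSide:
    @pytest.mark.parametrize(
        "cigar,start,expected",
        [
            ("50M50S", 1000, (1050, "right_clip")),
            ("50S50M", 1000, (1000, "left_clip")),
            ("10H90M", 1000, (1000, "left_clip")),
            ("40M10D50M10S", 1000, (1100, "right_clip")),  # M+D+M consume reference
            ("100M", 1000, None),
            ("60S30M10S", 1000, (1000, "left_clip")),  # longer clip wins
        ],
    )
    def test_clip_arithmetic(self, cigar, start, expected):
        assert junction_side(cigar, start) == expected


class TestCallSplitBreakpoints:
    def test_cigar_pair_example(self):
        pairs, _ = call_split_breakpoints(
            [_split("chr1", 1000, "50M50S", "+", "chr1", 200_000, "50S50M")]
        )
        (p,) = pairs
        assert (p.chrom_a, p.start_a) == ("chr1", 1050)
        assert (p.chrom_b, p.start_b) == ("chr1", 200_000)
        assert (p.side_a, p.side_b) == ("right_clip", "left_clip")
        assert p.evidence == "split" and p.support == 1

    def test_identical_tuples_aggregate(self):
        alignments = [
            _split("chr1", 1000, "50M50S", "+", "chr2", 80_000, "50S50M", name=f"r{i}")
            for i in range(7)
        ]
        pairs, _ = call_split_breakpoints(alignments)
        assert len(pairs) == 1 and pairs[0].support == 7

    def test_unclipped_records_are_counted_not_called(self):
        pairs, stats = call_split_breakpoints(
            [_split("chr1", 1000, "100M", "+", "chr2", 80_000, "50S50M")]
        )
        assert pairs == [] and stats["skipped_unclipped"] == 1

    def test_planted_junctions_recovered_exactly(self, bulk_fixture):
        splits, _, _ = classify_reads(bulk_fixture["bam"], DetectionParameters())
        pairs, _ = call_split_breakpoints(splits)
        called = {
            (p.chrom_a, p.start_a, p.chrom_b, p.start_b): p.support for p in pairs
        }
        for j in bulk_fixture["truth"]["junctions"]:
            ends = sorted(
                [(j["chrom_a"], j["pos_a"]), (j["chrom_b"], j["pos_b"])]
            )
            key = (*ends[0], *ends[1])
            assert called[key] == j["n_split"]
        assert len(called) == len(bulk_fixture["truth"]["junctions"])


class TestClusterDiscordant:
    def test_two_pairs_merge_with_wide_halfwidth(self):
        pairs = [
            _dpair("a", "chr1", 1000, "chr1", 300_000),
            _dpair("b", "chr1", 1400, "chr1", 300_600),
        ]
        clusters = cluster_discordant_pairs(pairs, 500)
        (c,) = clusters
        assert (c.start_a, c.end_a) == (500, 1901)  # covers [500, 1900]
        assert (c.start_b, c.end_b) == (299_500, 301_101)
        assert c.support == 2

    def test_same_pairs_split_with_narrow_halfwidth(self):
        pairs = [
            _dpair("a", "chr1", 1000, "chr1", 300_000),
            _dpair("b", "chr1", 1400, "chr1", 300_600),
        ]
        assert len(cluster_discordant_pairs(pairs, 100)) == 2

    def test_single_pair_degenerates_to_support_one(self):
        (c,) = cluster_discordant_pairs([_dpair("a", "chr1", 5, "chr2", 50)], 500)
        assert c.support == 1 and c.evidence == "discordant"

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_single_linkage(self, trial):
        rng = random.Random(1000 + trial)
        n = rng.randint(2, 200)
        pairs = [
            _dpair(
                f"p{i}",
                rng.choice(["chr1", "chr2"]),
                rng.randrange(0, 40_000),
                rng.choice(["chr1", "chr2"]),
                rng.randrange(0, 40_000),
            )
            for i in range(n)
        ]
        hw = rng.choice([100, 500, 1000])
        got = sorted(
            (c.chrom_a, c.start_a, c.end_a, c.chrom_b, c.start_b, c.end_b, c.support)
            for c in cluster_discordant_pairs(pairs, hw)
        )
        assert got == bruteforce_dual_clusters(pairs, hw)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        starts=st.lists(
            st.tuples(st.integers(0, 20_000), st.integers(0, 20_000)),
            min_size=1,
            max_size=40,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_order_invariance_and_support_conservation(self, starts, seed):
        pairs = [_dpair(f"p{i}", "chr1", a, "chr2", b) for i, (a, b) in enumerate(starts)]
        clusters = cluster_discordant_pairs(pairs, 500)
        assert sum(c.support for c in clusters) == len(pairs)
        shuffled = list(pairs)
        random.Random(seed).shuffle(shuffled)
        again = cluster_discordant_pairs(shuffled, 500)
        key = lambda c: (c.chrom_a, c.start_a, c.end_a, c.chrom_b, c.start_b, c.end_b, c.support)
        assert sorted(map(key, clusters)) == sorted(map(key, again))


class TestMergeAndCombine:
    def test_neighboring_split_pairs_merge_within_range(self):
        pairs, _ = call_split_breakpoints(
            [
                _split("chr1", 1000, "50M50S", "+", "chr2", 80_000, "50S50M", name="a"),
                _split("chr1", 1300, "50M50S", "+", "chr2", 80_400, "50S50M", name="b"),
                _split("chr1", 1050, "50M50S", "+", "chr2", 80_100, "50S50M", name="c"),
                _split("chr1", 1050, "50M50S", "+", "chr2", 80_100, "50S50M", name="d"),
            ]
        )
        merged = merge_neighboring_split_pairs(pairs, 1000)
        (m,) = merged
        assert m.support == 4
        # representative = highest-support member (the duplicated tuple)
        assert (m.start_a, m.start_b) == (1100, 80_100)

    def test_distant_split_pairs_stay_separate(self):
        pairs, _ = call_split_breakpoints(
            [
                _split("chr1", 1000, "50M50S", "+", "chr2", 80_000, "50S50M", name="a"),
                _split("chr1", 9000, "50M50S", "+", "chr2", 80_000, "50S50M", name="b"),
            ]
        )
        assert len(merge_neighboring_split_pairs(pairs, 1000)) == 2

    def test_split_inside_cluster_becomes_both(self):
        clusters = cluster_discordant_pairs(
            [_dpair(f"p{i}", "chr1", 1000 + 50 * i, "chr2", 80_000 + 50 * i) for i in range(5)],
            500,
        )
        split_pairs, _ = call_split_breakpoints(
            [_split("chr1", 1100, "50M50S", "+", "chr2", 80_050, "50S50M")]
        )
        combined = combine_split_and_discordant(split_pairs, clusters)
        (c,) = combined
        assert c.evidence == "both" and c.support == 6
        assert (c.split_pos_a, c.split_pos_b) == (1150, 80_050)

    def test_unmatched_split_passes_through(self):
        clusters = cluster_discordant_pairs([_dpair("p", "chr1", 1000, "chr2", 80_000)], 500)
        split_pairs, _ = call_split_breakpoints(
            [_split("chr1", 700_000, "50M50S", "+", "chr2", 900_000, "50S50M")]
        )
        combined = combine_split_and_discordant(split_pairs, clusters)
        assert len(combined) == 2
        assert {c.evidence for c in combined} == {"split", "discordant"}


def test_breakpoint_file_roundtrip(tmp_path):
    pairs = [
        BreakpointPair("chr1", 500, 1901, "chr1", 299_500, 301_101, "discordant", 12,
                       region_a_id=1, region_b_id=2, region_a_length=40_000,
                       region_b_length=30_000),
        BreakpointPair("chr2", 150_000, 150_001, "chr2", 180_000, 180_001, "split", 3),
    ]
    path = tmp_path / "bp.tsv"
    write_breakpoint_file(pairs, path)
    back = read_breakpoint_file(path)
    key = lambda p: (
        p.chrom_a, p.start_a, p.end_a, p.chrom_b, p.start_b, p.end_b,
        p.evidence, p.support, p.region_a_id, p.region_b_id,
        p.region_a_length, p.region_b_length,
    )
    assert sorted(map(key, back)) == sorted(map(key, pairs))


def test_empty_pair_list_writes_header_only(tmp_path):
    path = tmp_path / "bp.tsv"
    write_breakpoint_file([], path)
    assert path.read_text().count("\n") == 1
    assert read_breakpoint_file(path) == []
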