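import pytest

from multisv.consensus import (
    CensusError,
    ReplicateCensus,
    consensus_score,
    exclude_platform_calls,
    platform_frequency,
    score_records,
    select_high_confidence,
    select_initial,
    tenx_small_deletion_filter,
    tool_frequency,
)
from multisv.core import GenomicRegionSet, Provenance, SizeClassConfig, size_class_of
from multisv.merge import MergedSV

from .conftest import make_record

CFG = SizeClassConfig()


def census_3platform():
    """Scaled study census: 11-replicate short-read tools, single-replicate
    long-read tools."""
    return ReplicateCensus(
        {
            ("Illumina", "TNscope"): 11,
            ("Illumina", "Delly"): 11,
            ("Illumina", "Novobreak"): 11,
            ("Illumina", "Manta"): 11,
            ("PacBio", "Sniffles"): 1,
            ("PacBio", "PBSV"): 1,
            ("ONT", "Sniffles"): 1,
        }
    )


def merged_with_members(support):
    """support: list of (platform, tool, replicate) backing one deletion."""
    rec = make_record("m", "DEL", "chr1", 10_000, size=400)
    members = [
        (rec, Provenance(plat, tool, rep, "tumor")) for plat, tool, rep in support
    ]
    return MergedSV(representative=rec, members=members,
                    size_class=size_class_of(rec, CFG)[0])


class TestFrequencies:
    def test_tool_frequency_counts_distinct_replicates(self):
        sv = merged_with_members(
            [("Illumina", "Delly", str(i)) for i in range(1, 6)]
            + [("Illumina", "Delly", "1")]  # duplicate replicate
        )
        freqs = tool_frequency(sv, census_3platform())
        assert freqs == {("Illumina", "Delly"): 5 / 11}

    def test_single_replicate_tool_is_zero_or_one(self):
        sv = merged_with_members([("PacBio", "Sniffles", "1")])
        freqs = tool_frequency(sv, census_3platform())
        assert freqs[("PacBio", "Sniffles")] == 1
        assert ("PacBio", "PBSV") not in freqs  # absent, not a 0 entry

    def test_platform_frequency_uses_platform_denominator(self):
        sv = merged_with_members(
            [("Illumina", "TNscope", str(i)) for i in range(1, 12)]
        )
        pf = platform_frequency(sv, census_3platform())
        assert pf == {"Illumina": 11 / 44}

    def test_platform_frequency_one_of_two_single_replicate_tools(self):
        sv = merged_with_members([("PacBio", "Sniffles", "1")])
        pf = platform_frequency(sv, census_3platform())
        assert pf["PacBio"] == 1 / 2

    def test_full_support_gives_frequency_one(self):
        support = [
            ("Illumina", tool, str(i))
            for tool in ("TNscope", "Delly", "Novobreak", "Manta")
            for i in range(1, 12)
        ]
        pf = platform_frequency(merged_with_members(support), census_3platform())
        assert pf["Illumina"] == 1.0

    def test_unknown_provenance_raises(self):
        sv = merged_with_members([("Bionano", "Saphyr", "1")])
        with pytest.raises(CensusError):
            tool_frequency(sv, census_3platform())


class TestConsensusScore:
    def test_hand_computed_fixture(self):
        sv = merged_with_members(
            [("Illumina", "Delly", str(i)) for i in range(1, 6)]
            + [("Illumina", "Manta", str(i)) for i in range(1, 7)]
            + [("PacBio", "Sniffles", "1")]
        )
        freqs = tool_frequency(sv, census_3platform())
        assert freqs == {
            ("Illumina", "Delly"): 5 / 11,
            ("Illumina", "Manta"): 6 / 11,
            ("PacBio", "Sniffles"): 1.0,
        }
        assert consensus_score(freqs) == pytest.approx(2.0, abs=1e-9)

    def test_empty_map_scores_zero(self):
        assert consensus_score({}) == 0

    def test_score_bounded_by_tool_count(self):
        census = census_3platform()
        support = [
            (plat, tool, str(i))
            for (plat, tool), n in census.replicates.items()
            for i in range(1, n + 1)
        ]
        record = score_records([merged_with_members(support)], census)[0]
        assert record.consensus_score == pytest.approx(census.n_tools)
        assert all(0 <= f <= 1 for f in record.tool_freq.values())


class TestSelection:
    def test_replicate_threshold_and_blacklist(self):
        census = census_3platform()
        one_rep = merged_with_members([("Illumina", "Delly", "1")])
        two_rep = merged_with_members(
            [("Illumina", "Delly", "1"), ("Illumina", "Delly", "2")]
        )
        blacklisted = merged_with_members(
            [("Illumina", "Delly", str(i)) for i in range(1, 6)]
        )
        blacklist = GenomicRegionSet([("chr1", 0, 20_000)], "blacklist")
        records = score_records([one_rep, two_rep], census)
        kept = select_initial(records, blacklist=None)
        assert [r.merged for r in kept] == [two_rep]
        records = score_records([blacklisted], census)
        assert select_initial(records, blacklist=blacklist) == []

    def test_high_confidence_needs_two_platforms_and_two_tools(self):
        census = census_3platform()
        cases = {
            "two_plat_two_tool": (
                [("Illumina", "Manta", "1"), ("Illumina", "Manta", "2"),
                 ("PacBio", "Sniffles", "1")],
                True,
            ),
            "one_platform": (
                [("Illumina", "Manta", "1"), ("Illumina", "Delly", "1"),
                 ("Illumina", "Delly", "2")],
                False,
            ),
            "same_tool_name_two_platforms": (
                # Sniffles on PacBio and ONT are distinct tools
                [("PacBio", "Sniffles", "1"), ("ONT", "Sniffles", "1"),
                 ("PacBio", "Sniffles", "1")],
                True,
            ),
        }
        for name, (support, expect) in cases.items():
            records = score_records([merged_with_members(support)], census)
            initial = select_initial(records)
            if not initial:
                assert not expect, name
                continue
            high = select_high_confidence(initial)
            assert bool(high) == expect, name
            if high:
                assert high[0].high_confidence and high[0].initial

    def test_selection_chain_is_monotone(self):
        census = census_3platform()
        svs = [
            merged_with_members([("Illumina", "Delly", "1")]),
            merged_with_members(
                [("Illumina", "Delly", "1"), ("Illumina", "Delly", "2")]
            ),
            merged_with_members(
                [("Illumina", "Delly", "1"), ("Illumina", "Delly", "2"),
                 ("PacBio", "Sniffles", "1")]
            ),
        ]
        records = score_records(svs, census)
        initial = select_initial(records)
        high = select_high_confidence(initial)
        assert set(id(r) for r in high) <= set(id(r) for r in initial)
        assert set(id(r) for r in initial) <= set(id(r) for r in records)


class TestExclusions:
    def test_linked_read_small_deletions_removed(self):
        rec = make_record("d", "DEL", "chr1", 10_000, size=5_000)
        members = [
            (rec, Provenance("TenX", "LongRanger", "1", "tumor")),
        ]
        sv = MergedSV(representative=rec, members=members, size_class=3)
        assert exclude_platform_calls([sv], tenx_small_deletion_filter()) == []

    def test_matching_nothing_is_identity(self):
        sv = merged_with_members([("Illumina", "Delly", "1")])
        out = exclude_platform_calls([sv], tenx_small_deletion_filter())
        assert out == [sv]

    def test_recomputed_tool_count_never_increases(self):
        rec = make_record("d", "DEL", "chr1", 10_000, size=5_000)
        members = [
            (rec, Provenance("TenX", "LongRanger", "1", "tumor")),
            (rec, Provenance("Illumina", "Manta", "1", "tumor")),
        ]
        sv = MergedSV(representative=rec, members=members, size_class=3)
        (out,) = exclude_platform_calls([sv], tenx_small_deletion_filter())
        assert out.n_tools <= sv.n_tools
        assert out.n_tools == 1
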