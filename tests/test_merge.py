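"""Windowed merging and clustering, checked against an independent
brute-force oracle (pairwise predicate + transitive closure)."""

import numpy as np
import pytest

from multisv.core import CallSet, Provenance, SizeClassConfig, size_class_of
from multisv.merge import (
    MergedSV,
    cluster_merged,
    filter_regions,
    merge_calls,
    somatic_subtract,
    split_by_size_and_type,
)
from multisv.core import GenomicRegionSet

from .conftest import make_record, random_records

CFG = SizeClassConfig()


# -- independent oracle ------------------------------------------------------

def oracle_linkable(a, b, window, require_strict_sim=False):
    """Literal restatement of the merge rule, independent of the package's
    implementation: same type, chromosomes matching pairwise, both breakend
    offsets within the window; INS uses insertion-point distance plus >=50%
    size similarity; the clustering variant adds strict >50% similarity for
    all sized types."""
    if a.svtype != b.svtype:
        return False
    if a.bnd1.chrom != b.bnd1.chrom or a.bnd2.chrom != b.bnd2.chrom:
        return False
    sim = min(a.size, b.size) / max(a.size, b.size) if min(a.size, b.size) > 0 else 0
    if a.svtype == "INS":
        if abs(a.bnd1.pos - b.bnd1.pos) > window:
            return False
        return sim > 0.5 if require_strict_sim else sim >= 0.5
    if abs(a.bnd1.pos - b.bnd1.pos) > window or abs(a.bnd2.pos - b.bnd2.pos) > window:
        return False
    if a.svtype in ("TRA", "BND"):
        return True
    if require_strict_sim:
        return sim > 0.5
    return True


def transitive_closure(items, pred):
    """O(n^2) pairwise linking + closure by repeated sweeps."""
    n = len(items)
    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if pred(items[i], items[j]) and comp[i] != comp[j]:
                    tgt = min(comp[i], comp[j])
                    src = max(comp[i], comp[j])
                    comp = [tgt if c == src else c for c in comp]
                    changed = True
    groups = {}
    for i, c in enumerate(comp):
        groups.setdefault(c, []).append(i)
    return {frozenset(g) for g in groups.values()}


def partition_of_merged(merged, id_index):
    return {
        frozenset(id_index[rec.id] for rec, _ in m.members) for m in merged
    }


# -- merge_calls -------------------------------------------------------------

class TestMergeCalls:
    def test_two_nearby_deletions_merge(self, tumor_prov):
        a = make_record("a", "DEL", "chr1", 10_000, size=400)
        b = make_record("b", "DEL", "chr1", 10_050, size=380)
        merged = merge_calls([CallSet(tumor_prov, [a, b])], window=100)
        assert len(merged) == 1
        assert len(merged[0].members) == 2

    def test_same_coordinates_different_type_stay_apart(self, tumor_prov):
        a = make_record("a", "DEL", "chr1", 10_000, size=400)
        b = make_record("b", "DUP", "chr1", 10_000, size=400)
        merged = merge_calls([CallSet(tumor_prov, [a, b])], window=100)
        assert len(merged) == 2

    def test_window_must_be_positive(self, tumor_prov):
        with pytest.raises(ValueError):
            merge_calls([CallSet(tumor_prov, [])], window=0)

    def test_conservation_and_membership(self, rng, tumor_prov):
        records = random_records(rng, 30)
        merged = merge_calls([CallSet(tumor_prov, records)], window=200)
        assert sum(len(m.members) for m in merged) == len(records)
        for m in merged:
            assert any(rec is m.representative for rec, _ in m.members)
            assert len({rec.svtype for rec, _ in m.members}) == 1

    def test_matches_bruteforce_oracle(self, rng, tumor_prov):
        for trial in range(20):
            records = random_records(rng, int(rng.integers(5, 40)))
            id_index = {r.id: k for k, r in enumerate(records)}
            merged = merge_calls([CallSet(tumor_prov, records)], window=150)
            expected = transitive_closure(
                records, lambda a, b: oracle_linkable(a, b, 150)
            )
            assert partition_of_merged(merged, id_index) == expected

    def test_order_invariance(self, rng, tumor_prov):
        records = random_records(rng, 25)
        merged_fwd = merge_calls([CallSet(tumor_prov, records)], window=150)
        merged_rev = merge_calls(
            [CallSet(tumor_prov, list(reversed(records)))], window=150
        )
        key = lambda ms: sorted(
            frozenset(r.id for r, _ in m.members) for m in ms
        )
        assert key(merged_fwd) == key(merged_rev)


# -- somatic subtraction -----------------------------------------------------

class TestSomaticSubtract:
    def _merge_one(self, recs, prov, window=1000):
        return merge_calls([CallSet(prov, recs)], window)

    def test_matching_normal_removes_tumor_call(self, tumor_prov):
        normal_prov = Provenance("Illumina", "Manta", "1", "normal")
        t = self._merge_one([make_record("t", "DEL", "chr2", 5000, size=300)],
                            tumor_prov)
        n = self._merge_one([make_record("n", "DEL", "chr2", 5020, size=310)],
                            normal_prov)
        assert somatic_subtract(t, n, window=1000) == []

    def test_translocation_without_normal_counterpart_retained(self, tumor_prov):
        t = self._merge_one(
            [make_record("t", "TRA", "chr3", 1000, chrom2="chr17", pos2=2000)],
            tumor_prov, window=10_000,
        )
        assert somatic_subtract(t, [], window=10_000) == t

    def test_self_subtraction_empties(self, rng, tumor_prov):
        records = random_records(rng, 20)
        t = merge_calls([CallSet(tumor_prov, records)], window=150)
        assert somatic_subtract(t, t, window=150) == []


# -- clustering --------------------------------------------------------------

class TestClusterMerged:
    def _wrap(self, records, prov):
        return [
            MergedSV(representative=r, members=[(r, prov)],
                     size_class=size_class_of(r, CFG)[0])
            for r in records
        ]

    def test_similarity_just_above_half_clusters(self, tumor_prov):
        a = make_record("a", "DEL", "chr1", 10_000, size=100)
        b = make_record("b", "DEL", "chr1", 10_010, size=60)
        clustered = cluster_merged(self._wrap([a, b], tumor_prov), CFG)
        assert len(clustered) == 1

    def test_similarity_at_or_below_half_never_clusters(self, tumor_prov):
        a = make_record("a", "DEL", "chr1", 10_000, size=100)
        b = make_record("b", "DEL", "chr1", 10_000, size=50)  # exactly 0.5
        clustered = cluster_merged(self._wrap([a, b], tumor_prov), CFG)
        assert len(clustered) == 2

    def test_matches_bruteforce_oracle(self, rng, tumor_prov):
        def oracle_pred(a, b):
            if a.svtype in ("TRA", "BND") or b.svtype in ("TRA", "BND"):
                window = CFG.large_window
            else:
                ca, _ = CFG.class_of_size(a.size)
                cb, _ = CFG.class_of_size(b.size)
                window = CFG.window_of_class(min(ca, cb))
            return oracle_linkable(a, b, window, require_strict_sim=True)

        for trial in range(20):
            records = random_records(rng, int(rng.integers(5, 40)))
            id_index = {r.id: k for k, r in enumerate(records)}
            clustered = cluster_merged(self._wrap(records, tumor_prov), CFG)
            expected = transitive_closure(records, oracle_pred)
            assert partition_of_merged(clustered, id_index) == expected


# -- splitting and region filtering -----------------------------------------

class TestSplitAndFilter:
    def test_split_buckets_and_conservation(self, tumor_prov):
        recs = [
            make_record("a", "DEL", "chr1", 1000, size=80),
            make_record("b", "DEL", "chr1", 50_000, size=2000),
            make_record("c", "TRA", "chr1", 9000, chrom2="chr2", pos2=100),
        ]
        buckets = split_by_size_and_type(CallSet(tumor_prov, recs))
        assert len(buckets) == 3
        assert sum(len(cs.records) for cs in buckets.values()) == len(recs)
        for (idx, is_tra), cs in buckets.items():
            for r in cs.records:
                assert (r.svtype in ("TRA", "BND")) == is_tra

    def test_breakend_in_region_removes_cluster(self, tumor_prov):
        loh = GenomicRegionSet([("chr1", 0, 20_000)], "LOH")
        inside = make_record("a", "DEL", "chr1", 10_000, size=400)
        outside = make_record("b", "DEL", "chr1", 50_000, size=400)
        merged = merge_calls([CallSet(tumor_prov, [inside, outside])], 100)
        kept = filter_regions(merged, [loh])
        assert [m.representative.id for m in kept] == ["b"]

    def test_alt_contig_breakend_removed(self, tumor_prov):
        alt = make_record("a", "TRA", "chr1", 1000,
                          chrom2="chr1_KI270706v1_random", pos2=5000)
        merged = merge_calls([CallSet(tumor_prov, [alt])], 10_000)
        assert filter_regions(merged, []) == []

    def test_no_regions_primary_chroms_identity(self, rng, tumor_prov):
        merged = merge_calls([CallSet(tumor_prov, random_records(rng, 15))], 150)
        assert filter_regions(merged, []) == merged
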