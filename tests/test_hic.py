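import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multisv.hic import (
    ContactMatrix,
    balanced_contrast,
    classify_event,
    filter_candidates,
    find_candidates,
    quadrant_sums,
    refine_breakpoint,
    z_scores,
)
from multisv.simulate import GenomeModel, simulate_hic

from .conftest import make_record


def naive_quadrant_sums(C, i, j, R):
    """Independent cell-by-cell oracle for the quadrant formulas (the center
    cell belongs to both terms of each sum)."""
    n = C.shape[0]
    n_plus = n_minus = 0
    for k in range(i, i + R + 1):
        for l in range(j, j + R + 1):
            if 0 <= k < n and 0 <= l < n:
                n_plus += C[k, l]
    for k in range(i - R, i + 1):
        for l in range(j - R, j + 1):
            if 0 <= k < n and 0 <= l < n:
                n_plus += C[k, l]
    for k in range(i - R, i + 1):
        for l in range(j, j + R + 1):
            if 0 <= k < n and 0 <= l < n:
                n_minus += C[k, l]
    for k in range(i, i + R + 1):
        for l in range(j - R, j + 1):
            if 0 <= k < n and 0 <= l < n:
                n_minus += C[k, l]
    return n_plus, n_minus


def matrix_from(counts, w=50_000):
    n = counts.shape[0]
    M = ContactMatrix({"chr1": n * w}, w=w)
    M.counts = counts.astype(np.int64)
    return M


class TestBinning:
    def test_pair_increments_both_cells(self):
        M = ContactMatrix({"chr1": 200_000}, w=50_000)
        M.add_pair("chr1", 10, 30, "chr1", 60_010, 30)
        assert M.counts[0, 1] == 1 and M.counts[1, 0] == 1

    def test_low_mapq_pairs_rejected_and_counted(self):
        M = ContactMatrix({"chr1": 200_000}, w=50_000)
        M.add_pair("chr1", 10, 15, "chr1", 60_010, 30)
        M.add_pair("chr1", 10, 20, "chr1", 60_010, 30)  # threshold is strict
        assert M.counts.sum() == 0
        assert M.skipped["low_mapq"] == 2

    def test_mass_conservation(self, rng):
        sizes = {"chr1": 500_000, "chr2": 300_000}
        pairs = []
        for _ in range(200):
            c1, c2 = rng.choice(["chr1", "chr2"], size=2)
            pairs.append(
                (c1, int(rng.integers(1, sizes[c1])), 30,
                 c2, int(rng.integers(1, sizes[c2])), 30)
            )
        M = ContactMatrix.from_pairs(pairs, sizes)
        assert M.counts.sum() == 2 * len(pairs)
        M.validate_symmetry()

    def test_unknown_chromosome_skipped_with_counter(self):
        M = ContactMatrix({"chr1": 200_000}, w=50_000)
        M.add_pair("chrZ", 10, 30, "chr1", 10, 30)
        assert M.skipped["unknown_chrom"] == 1

    def test_triplet_round_trip(self, tmp_path, rng):
        g = GenomeModel.toy(n_chroms=2, length=500_000, blacklist_fraction=0)
        M = simulate_hic(g, w=50_000, depth=3.0, seed=4)
        path = tmp_path / "m.tsv"
        M.to_triplets(path)
        back = ContactMatrix.from_triplets(path)
        assert back.w == M.w and back.chrom_sizes == M.chrom_sizes
        assert np.array_equal(back.counts, M.counts)


class TestQuadrantStatistics:
    def test_all_ones_interior(self):
        M = matrix_from(np.ones((30, 30)))
        n_plus, n_minus = quadrant_sums(M, 15, 15, R=1)
        assert (n_plus, n_minus) == (8, 8)

    def test_zero_matrix(self):
        M = matrix_from(np.zeros((30, 30)))
        assert quadrant_sums(M, 3, 7, R=5) == (0, 0)

    def test_agrees_with_naive_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            C = rng.integers(0, 20, size=(30, 30))
            M = matrix_from(C)
            i, j = int(rng.integers(30)), int(rng.integers(30))
            R = int(rng.integers(1, 8))
            assert quadrant_sums(M, i, j, R) == naive_quadrant_sums(C, i, j, R)

    def test_symmetric_matrix_gives_symmetric_sums(self, rng):
        C = rng.integers(0, 10, size=(30, 30))
        C = C + C.T
        M = matrix_from(C)
        assert quadrant_sums(M, 5, 20, 4) == quadrant_sums(M, 20, 5, 4)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            quadrant_sums(matrix_from(np.ones((5, 5))), 1, 1, R=0)


class TestZScores:
    def test_printed_example(self):
        zp, zm = z_scores(16, 9)
        assert zp == pytest.approx(7 / 3)
        assert zm == pytest.approx(-7 / 4)

    def test_equal_counts_give_zero(self):
        assert z_scores(11, 11) == (0.0, 0.0)

    def test_zero_denominator_floored(self):
        zp, zm = z_scores(5, 0)
        assert zp == 5.0
        assert zm == pytest.approx(-5 / math.sqrt(5))

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_algebraic_identity(self, n_plus, n_minus):
        zp, zm = z_scores(n_plus, n_minus)
        lhs = zp
        rhs = -zm * math.sqrt(max(n_plus, 1) / max(n_minus, 1))
        assert lhs == pytest.approx(rhs, abs=1e-9)
        assert (zp >= 0) == (n_plus >= n_minus)


class TestCandidates:
    def test_zero_matrix_yields_none(self):
        g = GenomeModel.toy(n_chroms=2, length=2_000_000, blacklist_fraction=0)
        M = ContactMatrix(g.chromosomes, w=50_000)
        assert find_candidates(M) == []

    def test_implanted_junction_recovered_at_top(self):
        g = GenomeModel.toy(blacklist_fraction=0)
        tra = make_record("t", "TRA", "chr1", 5_000_000, chrom2="chr2",
                          pos2=8_000_000, info={"reciprocal": True})
        M = simulate_hic(g, w=50_000, depth=5.0, truth_svs=[tra],
                         signal_factor=5.0, seed=3)
        cands = find_candidates(M, R=10, Z_min=6.0)
        b1, b2 = M.bin_of("chr1", 5_000_000), M.bin_of("chr2", 8_000_000)
        top = cands[0]
        assert abs(top.i - b1) <= 1 and abs(top.j - b2) <= 1

    def test_two_distant_junctions_both_recovered(self):
        g = GenomeModel.toy(blacklist_fraction=0)
        tras = [
            make_record("t1", "TRA", "chr1", 4_000_000, chrom2="chr2",
                        pos2=6_000_000, info={"reciprocal": True}),
            make_record("t2", "TRA", "chr1", 14_000_000, chrom2="chr3",
                        pos2=10_000_000, info={"reciprocal": False}),
        ]
        M = simulate_hic(g, w=50_000, depth=5.0, truth_svs=tras,
                         signal_factor=5.0, seed=5)
        cands = filter_candidates(find_candidates(M, R=10, Z_min=6.0))
        found = set()
        for t in tras:
            b1 = M.bin_of(t.bnd1.chrom, t.bnd1.pos)
            b2 = M.bin_of(t.bnd2.chrom, t.bnd2.pos)
            for c in cands:
                if abs(c.i - b1) <= 1 and abs(c.j - b2) <= 1:
                    found.add(t.id)
        assert found == {"t1", "t2"}

    def test_candidates_sorted_by_score(self, rng):
        g = GenomeModel.toy(blacklist_fraction=0)
        M = simulate_hic(g, w=50_000, depth=5.0, seed=9)
        cands = find_candidates(M, Z_min=2.0)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)

    def test_filter_is_subset_order_preserving_and_identity_at_zero(self):
        g = GenomeModel.toy(n_chroms=2, length=5_000_000, blacklist_fraction=0)
        M = simulate_hic(g, w=50_000, depth=5.0, seed=2)
        cands = find_candidates(M, Z_min=1.0)
        assert filter_candidates(cands, 0, 0) == cands
        kept = filter_candidates(cands, 3.0, 10)
        ids = [(c.i, c.j) for c in cands]
        assert [(c.i, c.j) for c in kept] == [
            p for p, c in zip(ids, cands)
            if c.score >= 3 and max(c.n_plus, c.n_minus) >= 10
            and balanced_contrast(c.n_plus, c.n_minus) >= 3
        ]

    def test_low_mass_candidate_dropped(self):
        g = GenomeModel.toy(n_chroms=2, length=5_000_000, blacklist_fraction=0)
        M = ContactMatrix(g.chromosomes, w=50_000)
        M.counts[10, 60] = M.counts[60, 10] = 3  # 3 supporting pairs only
        cands = find_candidates(M, Z_min=1.0)
        assert cands
        assert filter_candidates(cands, min_score=0, min_quadrant_mass=10,
                                 min_balanced_z=0) == []


class TestRefinement:
    def test_noiseless_step_recovered_exactly(self):
        M = ContactMatrix({"chr1": 6_000_000, "chr2": 6_000_000}, w=10_000)
        b1, b2 = M.bin_of("chr1", 3_000_005), M.bin_of("chr2", 2_000_005)
        # junction signal: finite blocks on the NE and SW quadrants whose
        # shared corner sits exactly at (b1, b2)
        E = 20
        M.counts[b1 : b1 + E + 1, b2 : b2 + E + 1] = 5
        M.counts[b1 - E : b1 + 1, b2 - E : b2 + 1] = 5
        ref = refine_breakpoint(M, "chr1", 3_200_000, "chr2", 1_800_000)
        assert ref.bp1 == M.locus_of(b1)
        assert ref.bp2 == M.locus_of(b2)
        assert ref.kernel == "plus" and not ref.fallback

    def test_empty_submatrix_falls_back_flagged(self):
        M = ContactMatrix({"chr1": 6_000_000, "chr2": 6_000_000}, w=10_000)
        ref = refine_breakpoint(M, "chr1", 3_000_000, "chr2", 2_000_000)
        assert ref.fallback
        assert ref.bp1 == ("chr1", 3_000_000) and ref.bp2 == ("chr2", 2_000_000)

    def test_flat_background_tie_breaks_toward_plus_kernel(self):
        M = ContactMatrix({"chr1": 2_000_000, "chr2": 2_000_000}, w=10_000)
        lo2 = M.chrom_range("chr2")[0]
        M.counts[: M.chrom_range("chr1")[1], lo2:] = 2  # uniform inter block
        ref = refine_breakpoint(M, "chr1", 1_000_000, "chr2", 1_000_000,
                                half_window_bp=500_000)
        assert ref.kernel == "plus"


class TestClassification:
    def _inter_matrix(self):
        M = ContactMatrix({"chr1": 6_000_000, "chr2": 6_000_000}, w=50_000)
        return M, M.bin_of("chr1", 3_000_000), M.bin_of("chr2", 3_000_000)

    def test_reciprocal_translocation_from_opposite_quadrants(self):
        M, b1, b2 = self._inter_matrix()
        M.counts[b1 + 1 : b1 + 11, b2 + 1 : b2 + 11] = 10
        M.counts[b1 - 10 : b1, b2 - 10 : b2] = 10
        call = classify_event(M, "chr1", 3_000_000, "chr2", 3_000_000)
        assert call.event_class == "reciprocal_translocation"

    def test_single_quadrant_is_nonreciprocal(self):
        M, b1, b2 = self._inter_matrix()
        M.counts[b1 + 1 : b1 + 11, b2 + 1 : b2 + 11] = 10
        call = classify_event(M, "chr1", 3_000_000, "chr2", 3_000_000)
        assert call.event_class == "nonreciprocal_translocation"

    def test_all_four_quadrants_is_segmental_duplication(self):
        M, b1, b2 = self._inter_matrix()
        M.counts[b1 - 10 : b1 + 11, b2 - 10 : b2 + 11] = 10
        call = classify_event(M, "chr1", 3_000_000, "chr2", 3_000_000)
        assert call.event_class == "segmental_duplication"

    def test_intra_away_quadrant_is_deletion(self):
        M = ContactMatrix({"chr1": 12_000_000}, w=50_000)
        b1, b2 = M.bin_of("chr1", 4_000_000), M.bin_of("chr1", 8_000_000)
        M.counts[b1 - 10 : b1, b2 + 1 : b2 + 11] = 10
        M.counts[b2 + 1 : b2 + 11, b1 - 10 : b1] = 10
        call = classify_event(M, "chr1", 4_000_000, "chr1", 8_000_000)
        assert call.event_class == "deletion"

    def test_intra_butterfly_is_inversion(self):
        M = ContactMatrix({"chr1": 12_000_000}, w=50_000)
        b1, b2 = M.bin_of("chr1", 4_000_000), M.bin_of("chr1", 8_000_000)
        for r0, r1, c0, c1 in [
            (b1 + 1, b1 + 11, b2 + 1, b2 + 11),
            (b1 - 10, b1, b2 - 10, b2),
        ]:
            M.counts[r0:r1, c0:c1] = 10
            M.counts[c0:c1, r0:r1] = 10
        call = classify_event(M, "chr1", 4_000_000, "chr1", 8_000_000)
        assert call.event_class == "inversion"

    def test_no_elevation_reported_as_unclassified(self):
        M, _, _ = self._inter_matrix()
        call = classify_event(M, "chr1", 3_000_000, "chr2", 3_000_000)
        assert call.event_class == "unclassified"
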