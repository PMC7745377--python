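"""Matrix core: binning, coverage filter, KR/ICE balancing, expected, O/E."""

import time

import numpy as np
import pytest

from chromaforge.matrix import (BalancingError, ContactMatrix, ice_balance,
                                kr_balance)
from chromaforge.pairs import ReadAlignment, assign_pairs
from chromaforge.regions import GenomicRegion, RegionSet, make_bins
from chromaforge.simulate import SimulationConfig, simulate_matrix


@pytest.fixture
def small_bins():
    return make_bins({"chr1": 40}, 10)


class TestBinning:
    def test_pairs_accumulate_into_pixels(self, small_bins):
        frags = RegionSet([GenomicRegion("chr1", 0, 10), GenomicRegion("chr1", 10, 40)],
                          chromosome_lengths={"chr1": 40})
        alns = [(ReadAlignment("chr1", 2, "+"), ReadAlignment("chr1", 12, "-"))] * 3
        pairs = assign_pairs(alns, frags)
        m = ContactMatrix.from_pairs(pairs, small_bins, fragments=frags)
        i, j, v = m.pixels(norm=False)
        # fragment [10,40) has midpoint 25 -> bin 2
        assert list(i) == [0] and list(j) == [2] and list(v) == [3.0]

    def test_same_bin_pair_hits_diagonal(self, small_bins):
        frags = RegionSet([GenomicRegion("chr1", 0, 40)],
                          chromosome_lengths={"chr1": 40})
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 21, "+"), ReadAlignment("chr1", 24, "-"))], frags)
        m = ContactMatrix.from_pairs(pairs, small_bins, fragments=frags)
        i, j, v = m.pixels(norm=False)
        assert (i[0], j[0]) == (2, 2)

    def test_multiple_inputs_summed(self, small_bins):
        a = ContactMatrix.from_dense(small_bins, np.zeros((4, 4)))
        s1 = [(np.array([0]), np.array([1]), np.array([2.0]))]
        m1 = ContactMatrix(small_bins, s1[0])
        m2 = ContactMatrix(small_bins, (np.array([0]), np.array([1]), np.array([5.0])))
        i1, j1, v1 = m1.pixels(norm=False)
        i2, j2, v2 = m2.pixels(norm=False)
        merged = ContactMatrix(small_bins, (np.concatenate([i1, i2]),
                                            np.concatenate([j1, j2]),
                                            np.concatenate([v1, v2])))
        _, _, v = merged.pixels(norm=False)
        assert v.tolist() == [7.0]

    def test_unknown_chromosome_rejected(self, small_bins):
        frags = RegionSet([GenomicRegion("chrX", 0, 40)],
                          chromosome_lengths={"chrX": 40})
        pairs = assign_pairs(
            [(ReadAlignment("chrX", 5, "+"), ReadAlignment("chrX", 30, "-"))], frags)
        with pytest.raises(ValueError, match="chrX"):
            ContactMatrix.from_pairs(pairs, small_bins, fragments=frags)


class TestCoverageFilter:
    def _matrix(self, dense):
        bins = make_bins({"chr1": 10 * len(dense)}, 10)
        return ContactMatrix.from_dense(bins, np.asarray(dense, dtype=float))

    def test_relative_cutoff_uses_median_of_nonzero_marginals(self):
        # marginals [10, 2, 9, 11]: median 9.5, cutoff 2.375 -> bin 1 masked
        dense = np.array([
            [2.0, 1.0, 3.0, 4.0],
            [1.0, 0.0, 1.0, 0.0],
            [3.0, 1.0, 1.0, 4.0],
            [4.0, 0.0, 4.0, 3.0],
        ])
        m = self._matrix(dense)
        assert m.raw_marginals().tolist() == [10.0, 2.0, 9.0, 11.0]
        m.mask_low_coverage(rel_cutoff=0.25)
        assert m.mask.tolist() == [True, False, True, True]

    def test_uniform_marginals_nothing_masked(self):
        m = self._matrix(np.ones((4, 4)))
        m.mask_low_coverage(rel_cutoff=0.25)
        assert m.mask.all()

    def test_zero_marginal_bin_always_masked(self):
        dense = np.ones((3, 3))
        dense[1, :] = 0.0
        dense[:, 1] = 0.0
        m = self._matrix(dense)
        m.mask_low_coverage(cutoff=0.0)
        assert m.mask.tolist() == [True, False, True]

    def test_both_cutoffs_rejected(self):
        m = self._matrix(np.ones((3, 3)))
        with pytest.raises(ValueError):
            m.mask_low_coverage(cutoff=1.0, rel_cutoff=0.25)

    def test_drop_diagonals(self):
        m = self._matrix(np.ones((4, 4)))
        m.drop_diagonals(1)
        i, j, _ = m.pixels(norm=False)
        assert (j - i > 0).all()


class TestBalancing:
    def test_closed_form_two_by_two(self):
        # [[1,2],[2,4]] balances to all entries 1/2 with bias (1/sqrt2, 1/(2 sqrt2))
        a = np.array([[1.0, 2.0], [2.0, 4.0]])
        for kernel in (kr_balance, ice_balance):
            x = kernel(a)
            np.testing.assert_allclose(x, [1 / np.sqrt(2), 1 / (2 * np.sqrt(2))],
                                       atol=1e-12)
            np.testing.assert_allclose(np.diag(x) @ a @ np.diag(x), 0.5, atol=1e-12)

    def test_all_ones_gives_uniform_third(self):
        a = np.ones((3, 3))
        x = kr_balance(a)
        np.testing.assert_allclose(np.diag(x) @ a @ np.diag(x), 1 / 3, atol=1e-10)

    def test_zero_row_bin_masked_and_rest_balanced(self):
        bins = make_bins({"chr1": 30}, 10)
        dense = np.array([[1.0, 0.0, 2.0], [0.0, 0.0, 0.0], [2.0, 0.0, 1.0]])
        m = ContactMatrix.from_dense(bins, dense)
        assert m.mask.tolist() == [True, False, True]
        m.balance("kr")
        marg = m.marginals()
        assert np.isnan(marg[1])
        np.testing.assert_allclose(marg[[0, 2]], 1.0, atol=1e-9)

    def test_kr_and_ice_agree_on_positive_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.random((30, 30)) + 0.05
            a = a + a.T
            xk, xi = kr_balance(a), ice_balance(a)
            nk = np.diag(xk) @ a @ np.diag(xk)
            ni = np.diag(xi) @ a @ np.diag(xi)
            assert np.abs(nk - ni).max() <= 1e-5
            assert np.abs(nk.sum(axis=1) - 1).max() <= 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(BalancingError):
            kr_balance(np.array([[1.0, -2.0], [-2.0, 1.0]]))

    def test_per_chromosome_balancing_names_failing_chromosome(self):
        bins = make_bins({"good": 20, "bad": 20}, 10)
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 3.0
        dense[0, 0] = dense[1, 1] = 1.0
        # "bad" chromosome: disconnected support cannot be balanced
        dense[2, 2] = 1.0
        dense[3, 3] = 1.0
        m = ContactMatrix.from_dense(bins, dense)
        m.balance("kr")  # diagonal-only support is still balanceable per bin
        assert np.isfinite(m.bias[m.mask]).all()


class TestExpectedValues:
    def test_hand_built_diagonals(self, three_bin_matrix):
        e = three_bin_matrix.expected_values(norm=False).intra["chr1"]
        np.testing.assert_allclose(e, [5.0, 3.0, 1.0])

    def test_uniform_matrix_flat_profile(self):
        bins = make_bins({"chr1": 50}, 10)
        m = ContactMatrix.from_dense(bins, np.full((5, 5), 2.0))
        e = m.expected_values(norm=False).intra["chr1"]
        np.testing.assert_allclose(e, 2.0)

    def test_masked_bin_shrinks_denominator(self):
        bins = make_bins({"chr1": 30}, 10)
        dense = np.array([[5.0, 2.0, 0.0], [2.0, 5.0, 0.0], [0.0, 0.0, 0.0]])
        m = ContactMatrix.from_dense(bins, dense)
        assert not m.mask[2]
        e = m.expected_values(norm=False)
        # only one valid pair at distance 1: (0,1)
        assert e.intra_counts["chr1"][1] == 1
        assert e.intra["chr1"][1] == 2.0

    def test_sum_consistency_per_chromosome(self):
        config = SimulationConfig(seed=31, chromosome_lengths={"chr1": 1_000_000},
                                  bin_size=10_000)
        m, _ = simulate_matrix(config)
        e = m.expected_values(norm=False)
        i, j, v = m.pixels(norm=False)
        total = v.sum()
        recon = np.nansum(e.intra["chr1"] * e.intra_counts["chr1"])
        np.testing.assert_allclose(recon, total, rtol=1e-12)

    def test_no_intra_pixels_rejected(self):
        bins = make_bins({"a": 10, "b": 10}, 10)
        m = ContactMatrix(bins, (np.array([0]), np.array([1]), np.array([1.0])))
        with pytest.raises(ValueError):
            m.expected_values()


class TestOE:
    def test_expected_consistent_matrix_gives_unit_oe(self, three_bin_matrix):
        i, j, v = three_bin_matrix.oe_pixels()
        d = j - i
        e = three_bin_matrix.expected_values().intra["chr1"]
        np.testing.assert_allclose(v, three_bin_matrix.pixels()[2] / e[d])
        m = ContactMatrix.from_dense(make_bins({"c": 30}, 10), np.full((3, 3), 4.0))
        _, _, oe = m.oe_pixels()
        np.testing.assert_allclose(oe, 1.0)
        _, _, loe = m.oe_pixels(log2=True)
        np.testing.assert_allclose(loe, 0.0)

    def test_pixel_over_expected_arithmetic(self):
        bins = make_bins({"c": 30}, 10)
        dense = np.array([[0.0, 6.0, 0.0], [6.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        m = ContactMatrix.from_dense(bins, dense)
        i, j, v = m.oe_pixels()
        # e(1) = 6/2 = 3 on valid pairs (0,1),(1,2) -> pixel 6 maps to 2.0
        assert v[list(zip(i, j)).index((0, 1))] == pytest.approx(2.0)

    def test_masked_bins_emit_nothing(self, three_bin_matrix):
        three_bin_matrix.mask[1] = False
        three_bin_matrix.expected_profile = None
        i, j, _ = three_bin_matrix.oe_pixels()
        assert 1 not in set(i) | set(j)


class TestFetch:
    def test_whole_chromosome_dense_is_symmetric(self, three_bin_matrix):
        sub, rows, cols = three_bin_matrix.matrix("chr1")
        np.testing.assert_allclose(sub, sub.T)
        assert sub.shape == (3, 3)

    def test_single_anchor_virtual_4c_equals_matrix_row(self, three_bin_matrix):
        vals, cols = three_bin_matrix.virtual_4c("chr1:0-10")
        sub, _, _ = three_bin_matrix.matrix("chr1")
        np.testing.assert_allclose(vals, sub[0])

    def test_masked_anchor_bins_excluded_from_mean(self, three_bin_matrix):
        three_bin_matrix.mask[1] = False
        vals, _ = three_bin_matrix.virtual_4c("chr1:0-20")
        sub, _, _ = three_bin_matrix.matrix("chr1")
        np.testing.assert_allclose(vals, sub[0])  # only bin 0 contributes

    def test_region_outside_genome_rejected(self, three_bin_matrix):
        with pytest.raises((ValueError, KeyError)):
            three_bin_matrix.matrix("chr9")


class TestIO:
    def test_native_text_native_round_trip_value_exact(self, tmp_path, three_bin_matrix):
        m = three_bin_matrix
        t = tmp_path / "m.tsv"
        m.to_triplets(t)
        back = ContactMatrix.from_triplets(t, m.bins)
        np.testing.assert_array_equal(m.pixels(norm=False)[2],
                                      back.pixels(norm=False)[2])
        n = tmp_path / "m.cfm"
        back.save(n)
        again = ContactMatrix.load(n)
        np.testing.assert_array_equal(back.pixels(norm=False)[2],
                                      again.pixels(norm=False)[2])
        assert [str(r) for r in again.bins] == [str(r) for r in m.bins]

    def test_bedgraph2_round_trip(self, tmp_path, three_bin_matrix):
        p = tmp_path / "m.bg2"
        three_bin_matrix.to_bedgraph2(p, norm=False)
        back = ContactMatrix.from_bedgraph2(p, three_bin_matrix.bins)
        np.testing.assert_array_equal(three_bin_matrix.pixels(norm=False)[2],
                                      back.pixels(norm=False)[2])

    def test_native_preserves_bias_mask_metadata(self, tmp_path):
        config = SimulationConfig(seed=32, chromosome_lengths={"chr1": 500_000},
                                  bin_size=10_000)
        m, _ = simulate_matrix(config)
        m.balance("kr")
        p = tmp_path / "m.cfm"
        m.save(p)
        back = ContactMatrix.load(p)
        np.testing.assert_array_equal(m.bias, back.bias)
        np.testing.assert_array_equal(m.mask, back.mask)
        assert back.metadata["normalisation"] == "kr"


def test_pixel_iteration_throughput_is_fast():
    """Iterating a million-pixel matrix stays in the seconds range."""
    n = 1500
    rng = np.random.default_rng(0)
    i = rng.integers(0, n, size=1_000_000)
    j = rng.integers(0, n, size=1_000_000)
    bins = make_bins({"chr1": n * 10}, 10)
    m = ContactMatrix(bins, (i, j, np.ones(i.size)))
    t0 = time.time()
    ii, jj, vv = m.pixels(norm=True)
    total = vv.sum()
    assert time.time() - t0 < 5.0
    assert total > 0
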