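"""Insulation score, directionality index and boundary calling."""

import numpy as np
import pytest

from chromaforge.domains import (ScoreTrack, call_boundaries, directionality_index,
                                 insulation_score)
from chromaforge.matrix import ContactMatrix
from chromaforge.regions import make_bins


def _track(values, bin_size=10):
    values = np.asarray(values, dtype=float)
    bins = make_bins({"c": bin_size * values.size}, bin_size)
    return ScoreTrack(bins=bins, windows=[100], scores=values[:, None])


@pytest.fixture
def constant_matrix():
    bins = make_bins({"c": 300}, 10)
    return ContactMatrix.from_dense(bins, np.full((30, 30), 2.0))


@pytest.fixture
def two_block_matrix():
    """Two 20-bin TAD blocks: enriched within, depleted across the junction."""
    n = 40
    dense = np.full((n, n), 1.0)
    dense[:20, :20] = 5.0
    dense[20:, 20:] = 5.0
    bins = make_bins({"c": n * 10}, 10)
    return ContactMatrix.from_dense(bins, dense)


class TestInsulation:
    def test_constant_matrix_scores_zero_everywhere_defined(self, constant_matrix):
        for geom in (False, True):
            t = insulation_score(constant_matrix, [50], geometric_mean=geom)
            col = t.column(50)
            defined = np.isfinite(col)
            assert defined.any()
            np.testing.assert_allclose(col[defined], 0.0, atol=1e-12)

    def test_planted_junction_is_unique_local_minimum(self, two_block_matrix):
        t = insulation_score(two_block_matrix, [50])  # w = 5 bins
        col = t.column(50)
        defined = np.where(np.isfinite(col))[0]
        assert col[defined].argmin() + defined[0] in (19, 20)
        # the minimum is the symmetric junction plateau {19, 20} and nothing else
        m = np.nanmin(col)
        assert set(np.where(col == m)[0]) <= {19, 20}
        calls = call_boundaries(t, 50, min_score=0.5)
        assert [c.bin_index for c in calls] == [19]  # plateau centre (left-of-centre)

    def test_chromosome_edges_missing(self, constant_matrix):
        t = insulation_score(constant_matrix, [50])
        col = t.column(50)
        assert np.isnan(col[:5]).all() and np.isnan(col[-5:]).all()

    def test_window_below_two_bins_rejected(self, constant_matrix):
        with pytest.raises(ValueError, match="2 bins"):
            insulation_score(constant_matrix, [10])

    def test_scale_invariance(self, two_block_matrix):
        t1 = insulation_score(two_block_matrix, [50])
        i, j, v = two_block_matrix.pixels(norm=False)
        scaled = ContactMatrix(two_block_matrix.bins, (i, j, 10.0 * v))
        t2 = insulation_score(scaled, [50])
        ok = np.isfinite(t1.scores)
        np.testing.assert_allclose(t1.scores[ok], t2.scores[ok], atol=1e-9)

    def test_geometric_scores_at_least_arithmetic(self, two_block_matrix):
        # AM >= GM of raw scores, so log2(s/GM) >= log2(s/AM) bin-wise
        ta = insulation_score(two_block_matrix, [50], geometric_mean=False)
        tg = insulation_score(two_block_matrix, [50], geometric_mean=True)
        ok = np.isfinite(ta.scores)
        assert (tg.scores[ok] >= ta.scores[ok] - 1e-12).all()

    def test_masked_windows_missing_unless_imputed(self, two_block_matrix):
        two_block_matrix.mask[18:22] = False
        t = insulation_score(two_block_matrix, [50])
        assert np.isnan(t.column(50)[18:22]).all()
        ti = insulation_score(two_block_matrix, [50], impute=True)
        assert np.isfinite(ti.column(50)[10:30]).sum() > np.isfinite(
            t.column(50)[10:30]).sum()


class TestDirectionality:
    def test_symmetric_neighbourhood_gives_zero(self, constant_matrix):
        t = directionality_index(constant_matrix, [50])
        col = t.column(50)
        np.testing.assert_allclose(col[np.isfinite(col)], 0.0, atol=1e-12)

    def test_analytic_case_a1_b3(self):
        # A=1, B=3: E=2, DI = +((1-2)^2/2 + (3-2)^2/2) = +1
        n = 3
        dense = np.zeros((n, n))
        dense[1, 0] = dense[0, 1] = 1.0
        dense[1, 2] = dense[2, 1] = 3.0
        dense[0, 0] = dense[2, 2] = 1.0
        bins = make_bins({"c": 30}, 10)
        m = ContactMatrix.from_dense(bins, dense)
        t = directionality_index(m, [10])
        assert t.column(10)[1] == pytest.approx(1.0)

    def test_mirrored_matrix_negates_track(self, two_block_matrix):
        t = directionality_index(two_block_matrix, [30])
        dense, _, _ = two_block_matrix.matrix("c", norm=False)
        mirrored = ContactMatrix.from_dense(two_block_matrix.bins, dense[::-1, ::-1])
        tm = directionality_index(mirrored, [30])
        a, b = t.column(30), tm.column(30)[::-1]
        ok = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(a[ok], -b[ok], atol=1e-9)

    def test_scale_invariance(self, two_block_matrix):
        i, j, v = two_block_matrix.pixels(norm=False)
        scaled = ContactMatrix(two_block_matrix.bins, (i, j, 10.0 * v))
        t1 = directionality_index(two_block_matrix, [50])
        t2 = directionality_index(scaled, [50])
        ok = np.isfinite(t1.scores)
        # DI is a chi-square-like statistic: scales linearly, sign/zero pattern fixed
        np.testing.assert_allclose(np.sign(t1.scores[ok]), np.sign(t2.scores[ok]))


class TestBoundaries:
    def test_worked_example_score_and_cutoff(self):
        # minimum 0 flanked by maxima 1.2 and 1.8 -> score 1.5, passes 1.0
        t = _track([1.2, 0.5, 0.0, 0.9, 1.8, 0.2])
        calls = call_boundaries(t, 100, min_score=1.0)
        assert len(calls) == 1
        assert calls[0].bin_index == 2
        assert calls[0].score == pytest.approx(1.5)

    def test_min_combine_rule(self):
        t = _track([1.2, 0.5, 0.0, 0.9, 1.8, 0.2])
        calls = call_boundaries(t, 100, min_score=1.0, combine="min")
        assert len(calls) == 1 and calls[0].score == pytest.approx(1.2)

    def test_monotone_track_has_no_boundaries(self):
        t = _track(np.linspace(0, 3, 20))
        assert call_boundaries(t, 100, min_score=0.0) == []

    def test_plateau_minimum_collapses_to_central_bin(self):
        t = _track([2.0, 0.0, 0.0, 0.0, 2.0])
        calls = call_boundaries(t, 100, min_score=1.0)
        assert [c.bin_index for c in calls] == [2]
        # even plateau: left of centre
        t2 = _track([2.0, 0.0, 0.0, 2.0])
        calls2 = call_boundaries(t2, 100, min_score=1.0)
        assert [c.bin_index for c in calls2] == [1]

    def test_extrema_do_not_bridge_missing_gaps(self):
        t = _track([1.5, 0.0, np.nan, 0.0, 1.5, 0.0, 1.5])
        calls = call_boundaries(t, 100, min_score=1.0)
        # only the minimum at bin 5 has maxima on both sides within a segment
        assert [c.bin_index for c in calls] == [5]

    def test_entirely_missing_track_returns_empty(self, caplog):
        t = _track([np.nan] * 10)
        assert call_boundaries(t, 100, min_score=1.0) == []

    def test_planted_boundary_recovery(self, tad_matrix):
        matrix, truth = tad_matrix
        track = insulation_score(matrix, [100_000])
        calls = call_boundaries(track, 100_000, min_score=0.1)
        called = np.array([c.bin_index for c in calls])
        true_bins = np.array(sorted(b.index for b in truth["boundaries"]))
        hits = sum(np.abs(called - t).min() <= 1 for t in true_bins if called.size)
        assert hits / true_bins.size >= 0.9


class TestDifferenceTrackBoundaries:
    def test_difference_of_identical_tracks_has_no_boundaries(self, two_block_matrix):
        from chromaforge.comparisons import compare

        t = insulation_score(two_block_matrix, [50])
        diff = compare(t, t, "difference")
        assert call_boundaries(diff, 50, min_score=1e-9) == []
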