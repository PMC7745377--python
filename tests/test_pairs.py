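"""Pair module: junction splitting, fragment assignment, the filter suite."""

import itertools

import numpy as np
import pytest

from chromaforge.pairs import (FILTER_ORDER, FilterConfig, ReadAlignment,
                               assign_pairs, filter_pairs, ligation_error_curves,
                               pair_diagnostics, read_pairs, split_at_junction,
                               write_pairs)
from chromaforge.regions import GenomicRegion, RegionSet
from chromaforge.simulate import SimulationConfig, simulate_pairs


@pytest.fixture
def fragments():
    return RegionSet(
        [GenomicRegion("chr1", 0, 10), GenomicRegion("chr1", 10, 40),
         GenomicRegion("chr1", 40, 100), GenomicRegion("chr2", 0, 50)],
        chromosome_lengths={"chr1": 100, "chr2": 50},
    )


class TestJunctionSplit:
    def test_split_restores_site_on_both_flanks(self):
        x, y = "A" * 30, "C" * 30
        subs = split_at_junction(x + "GATCGATC" + y, "GATCGATC")
        assert subs == [x + "GATC", "GATC" + y]

    def test_read_without_junction_unchanged(self):
        read = "ACGT" * 10
        assert split_at_junction(read, "GATCGATC") == [read]

    def test_short_flank_discarded(self):
        read = "AAAA" + "GATCGATC" + "C" * 30  # left flank 4+4=8 < 20
        subs = split_at_junction(read, "GATCGATC")
        assert subs == ["GATC" + "C" * 30]

    def test_multiple_junctions(self):
        a, b, c = "A" * 25, "T" * 25, "G" * 25
        subs = split_at_junction(a + "GATCGATC" + b + "GATCGATC" + c, "GATCGATC")
        assert len(subs) == 3


class TestAssignment:
    def test_inward_orientation_and_fragments(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr1", 30, "-"))],
            fragments)
        p = pairs[0]
        assert (p.left.fragment, p.right.fragment) == (0, 1)
        assert p.orientation == "inward"
        # + read faces downstream edge (10), - read faces upstream edge (10)
        assert p.left.re_distance == 5
        assert p.right.re_distance == 20

    def test_same_fragment_candidate_self_ligation(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 12, "-"), ReadAlignment("chr1", 30, "+"))],
            fragments)
        assert pairs[0].left.fragment == pairs[0].right.fragment == 1

    def test_inter_chromosomal_pair(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr2", 5, "-"))],
            fragments)
        assert not pairs[0].is_intra
        assert pairs[0].separation is None

    def test_unknown_chromosome_flagged_unmappable(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chrX", 5, "+"), ReadAlignment("chr1", 5, "-"))],
            fragments)
        assert pairs[0].left.is_unmapped or pairs[0].right.is_unmapped


class TestFilters:
    def test_low_mapq_removed_at_default_threshold(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+", mapq=2),
              ReadAlignment("chr1", 60, "-", mapq=60))], fragments)
        valid, stats = filter_pairs(pairs, FilterConfig(density_quantile=100))
        assert stats.removed["quality"] == 1 and stats.valid == 0

    def test_short_inward_pair_is_ligation_error(self, fragments):
        # inward, restriction-site separation 4000 < 5000 default cutoff
        frags = RegionSet([GenomicRegion("chr1", 0, 1000),
                           GenomicRegion("chr1", 1000, 5000),
                           GenomicRegion("chr1", 5000, 20000)],
                          chromosome_lengths={"chr1": 20000})
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 500, "+"), ReadAlignment("chr1", 6000, "-"))],
            frags)
        assert pairs[0].separation == 4000
        valid, stats = filter_pairs(pairs, FilterConfig(density_quantile=100))
        assert stats.removed["ligation_error"] == 1

    def test_duplicate_keeps_first_seen(self, fragments):
        alns = [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr1", 60, "-"))] * 2
        pairs = assign_pairs(alns, fragments)
        valid, stats = filter_pairs(
            pairs, FilterConfig(density_quantile=100, inward_cutoff=0))
        assert stats.valid == 1 and stats.removed["pcr_duplicate"] == 1

    def test_self_ligation_removes_all_and_only_same_fragment(self, fragments):
        alns = [
            (ReadAlignment("chr1", 12, "-"), ReadAlignment("chr1", 30, "+")),  # same frag
            (ReadAlignment("chr1", 5, "-"), ReadAlignment("chr1", 60, "+")),   # outward, far
        ]
        pairs = assign_pairs(alns, fragments)
        valid, stats = filter_pairs(
            pairs, FilterConfig(density_quantile=100, outward_cutoff=0))
        assert stats.removed["self_ligation"] == 1
        assert valid[0].left.fragment != valid[0].right.fragment

    def test_inter_chromosomal_bypasses_distance_filters(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 9, "+"), ReadAlignment("chr2", 1, "-"))],
            fragments)
        valid, stats = filter_pairs(
            pairs, FilterConfig(density_quantile=100, re_distance_cutoff=None))
        assert stats.valid == 1

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(inward_cutoff=-1)

    def test_custom_predicate_filter(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr1", 60, "-")),
             (ReadAlignment("chr2", 5, "+"), ReadAlignment("chr2", 30, "-"))],
            fragments)
        config = FilterConfig(density_quantile=100, inward_cutoff=0,
                              filter_self_ligations=False,
                              custom_filters=[("chr1_only",
                                               lambda p: p.left.chromosome != "chr2")])
        valid, stats = filter_pairs(pairs, config)
        assert stats.removed["chr1_only"] == 1 and stats.valid == 1


@pytest.fixture(scope="module")
def planted():
    config = SimulationConfig(
        seed=21, n_pairs=10_000, chromosome_lengths={"chr1": 5_000_000},
        artefact_fractions={"pcr_duplicate": 0.05, "self_ligation": 0.05,
                            "inward_error": 0.04, "outward_error": 0.03,
                            "low_quality": 0.02, "unmapped": 0.01})
    pairs, truth, frags = simulate_pairs(config)
    valid, stats = filter_pairs(pairs, FilterConfig(density_quantile=100))
    return pairs, truth, valid, stats


class TestPlantedArtefacts:
    def test_each_filter_count_equals_planted_count(self, planted):
        _, truth, _, stats = planted
        assert stats.removed["pcr_duplicate"] == truth["pcr_duplicate"]
        assert stats.removed["self_ligation"] == truth["self_ligation"]
        assert stats.removed["ligation_error"] == (
            truth["inward_error"] + truth["outward_error"])
        assert stats.removed["quality"] == truth["low_quality"]
        assert stats.removed["unmapped"] == truth["unmapped"]
        assert stats.valid == truth["valid"]

    def test_conservation_total_equals_valid_plus_removed(self, planted):
        _, truth, _, stats = planted
        assert stats.total == stats.valid + sum(stats.removed.values())

    def test_filter_counts_stable_under_input_permutation(self, planted):
        pairs, _, _, stats = planted
        rng = np.random.default_rng(0)
        order = rng.permutation(len(pairs))
        # keep duplicate copies after their sources: permute only valid block
        n_valid_src = stats.valid
        shuffled = [pairs[i] for i in order if i < n_valid_src] \
            + [pairs[i] for i in range(n_valid_src, len(pairs))]
        _, stats2 = filter_pairs(shuffled, FilterConfig(density_quantile=100))
        assert stats2.removed == stats.removed


class TestDiagnostics:
    def test_random_orientations_converge_to_quarter(self):
        config = SimulationConfig(seed=22, n_pairs=20_000,
                                  chromosome_lengths={"chr1": 5_000_000})
        pairs, _, _ = simulate_pairs(config)
        curves = ligation_error_curves(pairs)
        # at separations well above the fragment-scale discreteness, every
        # orientation fraction sits in a binomial band around 0.25
        big = curves[(curves["n"] >= 100) & (curves["separation"] > 20_000)]
        assert len(big) >= 3
        for o in ("inward", "outward", "same-forward", "same-reverse"):
            se = np.sqrt(0.25 * 0.75 / big["n"])
            assert (np.abs(big[o] - 0.25) < 5 * se + 1e-9).all()

    def test_planted_inward_excess_below_cutoff_only(self):
        config = SimulationConfig(
            seed=23, n_pairs=20_000, chromosome_lengths={"chr1": 5_000_000},
            artefact_fractions={"inward_error": 0.3})
        pairs, _, _ = simulate_pairs(config)
        curves = ligation_error_curves(pairs)
        low = curves[curves["separation"] < 2000]
        high = curves[(curves["separation"] > 20_000) & (curves["n"] >= 100)]
        assert (low["inward"] > 0.9).all()
        assert np.abs(np.average(high["inward"], weights=high["n"]) - 0.25) < 0.05

    def test_empty_pair_set_yields_empty_diagnostics(self):
        stats = pair_diagnostics([])
        assert len(stats.ligation_error_curves) == 0
        assert stats.median_insert_size is None

    def test_median_insert_size_reported(self, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr1", 60, "-"))],
            fragments)
        stats = pair_diagnostics(pairs)
        # + at 5 faces edge 10 (dist 5); - at 60 faces edge 40 (dist 20)
        assert stats.median_insert_size == 25


class TestPairIO:
    def test_text_round_trip(self, tmp_path, fragments):
        pairs = assign_pairs(
            [(ReadAlignment("chr1", 5, "+"), ReadAlignment("chr1", 60, "-")),
             (ReadAlignment("chr1", 15, "-"), ReadAlignment("chr2", 10, "+"))],
            fragments)
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        back = read_pairs(path, fragments)
        for a, b in zip(pairs, back):
            assert (a.left.position, a.right.position) == (b.left.position, b.right.position)
            assert a.orientation == b.orientation
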