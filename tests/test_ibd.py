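import numpy as np
import pytest

from haploscan.cohort_sim import SimConfig, gene_drop, simulate_founders
from haploscan.cohort_sim.pedigree import FEMALE, MALE, Member, Pedigree
from haploscan.datatypes import MarkerMap
from haploscan.errors import ValidationError
from haploscan.ibd_segments import (
    IBDParams,
    IBDSegment,
    call_ibd_segments,
    relationship_calibration,
    summarize_sharing,
)

from tests.oracles import recount_sharing

PARAMS = IBDParams(min_length_bp=2_500_000, min_markers=50)


def _pair_from_genedrop(relationship, seed, length=50_000_000, density=30.0,
                        cm_per_mb=1.0):
    """Simulate one related pair on one chromosome; returns genotype
    vectors, the map, frequencies and truth."""
    config = SimConfig(genome=[("1", length)], marker_density_per_mb=density,
                       founder_maf_min=0.2, cm_per_mb=cm_per_mb, seed=seed)
    members = [
        Member("F", None, None, MALE),
        Member("M", None, None, FEMALE),
    ]
    if relationship == "parent_offspring":
        members.append(Member("A", "F", "M", MALE))
        pair = ("F", "A")
    elif relationship == "sibs":
        members += [Member("A", "F", "M", MALE), Member("B", "F", "M", FEMALE)]
        pair = ("A", "B")
    else:
        raise AssertionError(relationship)
    ped = Pedigree(members)
    founders = simulate_founders(config, 2)
    cohort, truth = gene_drop(ped, founders, config)
    g = cohort.genotypes()
    return (
        g[cohort.index_of(pair[0])],
        g[cohort.index_of(pair[1])],
        founders.marker_map,
        founders.frequencies,
        truth,
        pair,
    )


class TestCaller:
    def test_twins_give_single_ibd2_segment_per_chromosome(self, rng):
        config = SimConfig(genome=[("1", 30_000_000), ("2", 30_000_000)],
                           founder_maf_min=0.2, seed=1)
        founders = simulate_founders(config, 1)
        g = founders.haplotypes[0] + founders.haplotypes[1]
        segs = call_ibd_segments(g, g.copy(), founders.marker_map, PARAMS,
                                 allele_freq=founders.frequencies)
        assert len(segs) == 2
        assert all(s.state == "IBD2" for s in segs)
        for s, chrom in zip(segs, ("1", "2")):
            idx = founders.marker_map.chrom_indices(chrom)
            assert s.start_bp == founders.marker_map.pos[idx[0]]
            assert s.end_bp == founders.marker_map.pos[idx[-1]]

    def test_parent_offspring_near_full_coverage(self):
        ga, gb, marker_map, freqs, _, _ = _pair_from_genedrop("parent_offspring", 2)
        segs = call_ibd_segments(ga, gb, marker_map, PARAMS, allele_freq=freqs)
        covered = sum(s.length_bp for s in segs)
        assert covered > 0.95 * 50_000_000
        assert all(s.state == "IBD1" for s in segs)

    def test_planted_segment_recovered_with_tight_boundaries(self):
        # two unrelated individuals; copy a 10 Mb block from A to B
        config = SimConfig(genome=[("1", 50_000_000)], founder_maf_min=0.2, seed=3)
        founders = simulate_founders(config, 2)
        a0, a1 = founders.haplotypes[0], founders.haplotypes[1]
        b0, b1 = founders.haplotypes[2].copy(), founders.haplotypes[3]
        sel = (founders.marker_map.pos >= 20_000_000) & (founders.marker_map.pos < 30_000_000)
        b0[sel] = a0[sel]
        ga, gb = a0 + a1, b0 + b1
        segs = call_ibd_segments(ga, gb, founders.marker_map,
                                 IBDParams(min_length_bp=5_000_000, min_markers=100),
                                 allele_freq=founders.frequencies)
        assert len(segs) == 1
        s = segs[0]
        assert abs(s.start_bp - 20_000_000) < 500_000
        assert abs(s.end_bp - 30_000_000) < 500_000

    def test_symmetry(self):
        ga, gb, marker_map, freqs, _, _ = _pair_from_genedrop("sibs", 4)
        s1 = call_ibd_segments(ga, gb, marker_map, PARAMS, allele_freq=freqs)
        s2 = call_ibd_segments(gb, ga, marker_map, PARAMS, allele_freq=freqs)
        assert [(s.chrom, s.start_bp, s.end_bp, s.state) for s in s1] == [
            (s.chrom, s.start_bp, s.end_bp, s.state) for s in s2
        ]

    def test_segments_never_overlap(self):
        for seed in range(5):
            ga, gb, marker_map, freqs, _, _ = _pair_from_genedrop("sibs", 100 + seed)
            segs = call_ibd_segments(ga, gb, marker_map, PARAMS, allele_freq=freqs)
            by_chrom = {}
            for s in segs:
                by_chrom.setdefault(s.chrom, []).append((s.start_bp, s.end_bp))
            for intervals in by_chrom.values():
                intervals.sort()
                for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
                    assert e0 <= s1

    def test_min_length_monotonicity(self):
        ga, gb, marker_map, freqs, _, _ = _pair_from_genedrop("sibs", 6)
        counts = []
        for min_mb in (1.0, 2.5, 5.0, 10.0):
            p = IBDParams(min_length_bp=min_mb * 1e6, min_markers=10)
            counts.append(len(call_ibd_segments(ga, gb, marker_map, p,
                                                allele_freq=freqs)))
        assert counts == sorted(counts, reverse=True)

    def test_mismatched_map_rejected(self, rng):
        marker_map = MarkerMap(np.array(["1"] * 5, object),
                               np.arange(1, 6) * 1000, np.array(list("abcde"), object))
        with pytest.raises(ValidationError):
            call_ibd_segments(np.zeros(4, np.int8), np.zeros(5, np.int8), marker_map)


class TestSummary:
    def test_threshold_band_arithmetic(self):
        segs = [
            IBDSegment("a", "b", "1", 0 + 1, int(19.1e6) + 1, "IBD1"),
            IBDSegment("a", "b", "2", 1, 12_000_001, "IBD1"),
            IBDSegment("a", "b", "3", 1, 8_000_001, "IBD1"),
            IBDSegment("a", "b", "4", 1, 3_000_001, "IBD1"),
        ]
        summary = summarize_sharing(segs)
        assert summary.total_mb_over_hi == pytest.approx(39.1)
        assert summary.n_segments_over_hi == 3
        assert summary.longest_mb == pytest.approx(19.1)
        assert summary.total_mb_band == pytest.approx(3.0)
        assert summary.n_segments_band == 1

    def test_empty_list(self):
        summary = summarize_sharing([], focal=("1", 1000))
        assert summary.total_mb_over_hi == 0
        assert summary.longest_mb == 0
        assert summary.focal_segment is None

    def test_focal_segment_lookup(self):
        segs = [IBDSegment("a", "b", "7", 100, 6_000_100, "IBD1")]
        assert summarize_sharing(segs, focal=("7", 5_000_000)).focal_segment is segs[0]
        assert summarize_sharing(segs, focal=("7", 7_000_000)).focal_segment is None
        assert summarize_sharing(segs, focal=("1", 5_000_000)).focal_segment is None

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_match_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        segs = []
        for k in range(30):
            start = int(rng.integers(1, 10_000_000))
            length = int(rng.integers(100_000, 25_000_000))
            segs.append(IBDSegment("a", "b", str(k), start, start + length, "IBD1"))
        summary = summarize_sharing(segs)
        expected = recount_sharing([s.length_mb for s in segs])
        assert summary.total_mb_over_hi == pytest.approx(expected["total_over"])
        assert summary.n_segments_over_hi == expected["n_over"]
        assert summary.longest_mb == pytest.approx(expected["longest"])
        assert summary.total_mb_band == pytest.approx(expected["total_band"])
        assert summary.n_segments_band == expected["n_band"]


class TestCalibration:
    def test_siblings_share_three_quarters(self):
        result = relationship_calibration(degree=0, n_pairs=150, seed=1)
        # P(>=1 shared haplotype) = 3/4 of the genome in expectation
        assert abs(result.mean_fraction - 0.75) < 3 * result.se_fraction + 0.01

    def test_third_cousins_truth_fraction(self):
        # scaled-down version of the acceptance run (500 pairs there): the
        # allele-sharing proportion has expectation 2 * (1/2)^8 = 1/128
        result = relationship_calibration(degree=3, n_pairs=150, seed=2)
        assert abs(result.mean_allele_fraction - 1 / 128) < (
            3 * result.se_allele_fraction + 0.001
        )
        # the >=1-haplotype fraction has expectation (1/2)^6 = 1/64
        assert abs(result.mean_fraction - 1 / 64) < 3 * result.se_fraction + 0.002

    def test_zero_recombination_all_or_nothing(self):
        # without crossovers a single chromosome is shared entirely or not
        # at all; P(first cousins share >= 1 haplotype) enumerates to 1/4
        result = relationship_calibration(degree=1, n_pairs=400, seed=3,
                                          genome=[("1", 10_000_000)], cm_per_mb=0.0)
        assert set(np.round(np.unique(result.fractions), 6)) <= {0.0, 1.0}
        assert abs(result.mean_fraction - 0.25) < 3 * result.se_fraction + 0.01

    def test_caller_mode_close_to_truth_for_sibs(self):
        truth = relationship_calibration(degree=0, n_pairs=25, seed=4,
                                         genome=[("1", 50_000_000)])
        called = relationship_calibration(degree=0, n_pairs=25, seed=4,
                                          genome=[("1", 50_000_000)],
                                          marker_density_per_mb=30.0,
                                          use_caller=True,
                                          params=IBDParams(min_length_bp=2.5e6,
                                                           min_markers=50))
        # the caller cannot report segments below its length threshold, so
        # it may only under-cover the truth, and not by much
        assert called.mean_fraction <= truth.mean_fraction + 0.02
        assert called.mean_fraction > truth.mean_fraction - 0.25

    def test_negative_degree_rejected(self):
        with pytest.raises(ValidationError):
            relationship_calibration(degree=-1, n_pairs=10, seed=0)
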