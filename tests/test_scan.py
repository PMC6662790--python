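import numpy as np
import pytest

from haploscan.cohort_sim import (
    KindredSpec,
    PedigreeSpec,
    SimConfig,
    simulate_cohort,
)
from haploscan.datatypes import MISSING, FocalVariant
from haploscan.errors import ValidationError, WindowError
from haploscan.haplotype_scan import (
    coarse_sweep,
    define_carrier_haplotype,
    fine_extend,
    haplotype_background_frequency,
    scan_cohort,
)

from tests.conftest import make_cohort_from_haps, make_random_cohort
from tests.oracles import brute_define, brute_fine, brute_scan


def _scan_order(positions, focal):
    return sorted(range(len(positions)),
                  key=lambda j: (abs(positions[j] - focal), positions[j]))


class TestDefine:
    def test_single_carrier_is_ambiguous_with_both_haplotypes(self, rng):
        cohort, marker_map = make_random_cohort(4, 20, rng)
        focal = FocalVariant("1", 100_000, ["I000"])
        result = define_carrier_haplotype(cohort, marker_map, focal, 200_000)
        assert result.status == "ambiguous"
        strings = {c.alleles.tobytes() for c in result.candidates}
        i0 = cohort.alleles[0]
        idx = result.candidates[0].marker_indices
        assert strings == {i0[idx, 0].tobytes(), i0[idx, 1].tobytes()}

    def test_planted_shared_segment_recovers_founder_string(self):
        config = SimConfig(
            genome=[("1", 20_000_000)],
            pedigree_spec=PedigreeSpec([KindredSpec(3, 3.0)]),
            seed=21,
        )
        sim = simulate_cohort(config, founder_hap_label=0,
                              require_known_kindred_carriers=3,
                              min_flank_mb=0.5)
        carriers = sim.recorded_carrier_ids[:3]
        focal = sim.variant.as_focal(carriers)
        result = define_carrier_haplotype(sim.cohort, sim.marker_map, focal, 400_000)
        assert result.ok
        cand = result.candidates[0]
        founder_hap = sim.founders.haplotypes[sim.variant.founder_hap_label]
        full_idx = [list(sim.full_map.ids).index(m) for m in sim.marker_map.ids[cand.marker_indices]]
        resolved = cand.alleles != MISSING
        assert np.array_equal(cand.alleles[resolved],
                              founder_hap[full_idx][resolved])

    def test_breakpoint_inside_window_reports_discordant_marker(self):
        # 3 carriers share the consensus 111... except carrier 2 breaks to
        # the 0-haplotype beyond marker index 6 on both of its haplotypes
        m = 11
        ones, zeros = [1] * m, [0] * m
        broken = [1] * 7 + [0] * (m - 7)
        rows = [
            (ones, zeros),
            (ones, zeros),
            (broken, broken),
            (zeros, zeros),
        ]
        cohort, marker_map = make_cohort_from_haps(rows)
        focal = FocalVariant("1", 60_000, ["I000", "I001", "I002"])
        result = define_carrier_haplotype(cohort, marker_map, focal, 120_000)
        assert result.status == "no_consensus"
        # verify against exhaustive assignment search
        idx = marker_map.window_indices("1", 0, 120_000)
        order = _scan_order(marker_map.pos[idx], 60_000)
        pairs = [cohort.alleles[i][idx].tolist() for i in range(3)]
        status, _ = brute_define(pairs, order)
        assert status == "no_consensus"
        # first marker past the breakpoint (scanning out from the focal) is
        # the last marker of the window on the right: index 7 at 80 kb
        assert result.discordant_marker[1] == 80_000

    def test_empty_window_is_error(self, rng):
        cohort, marker_map = make_random_cohort(3, 10, rng)
        focal = FocalVariant("1", 55_000, ["I000"])
        with pytest.raises(WindowError):
            define_carrier_haplotype(cohort, marker_map, focal, 2)


class TestScan:
    def test_known_carriers_match_their_own_consensus(self, rng):
        cohort, marker_map = make_random_cohort(8, 30, rng)
        focal = FocalVariant("1", 150_000, ["I001", "I002"])
        result = define_carrier_haplotype(cohort, marker_map, focal, 40_000)
        if result.ok:
            # re-scan including the carriers by faking a different source set
            for cand in result.candidates:
                cand2 = type(cand)(
                    cand.chrom, cand.window_start_bp, cand.window_end_bp,
                    cand.marker_indices, cand.alleles, ["nobody"], {},
                )
                hits = {m.individual_id for m in scan_cohort(cohort, marker_map, cand2)}
                for c in focal.known_carrier_ids:
                    assert c in hits

    def test_hand_built_fixture_with_planted_matches(self):
        m = 12
        consensus = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1]
        other = [0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0]
        other2 = [1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 1, 0]  # clashes with both
        near = list(consensus)
        near[0] = 0   # differs only at the leftmost marker
        near[-1] = 1 if consensus[-1] == 0 else 0
        rows = [
            (consensus, other),   # I000: carrier
            (other2, consensus),  # I001: carrier
            (consensus, other),   # I002: planted match
            (other, consensus),   # I003: planted match
            (near, other),        # I004: matches only inner windows
            (other, other),       # I005
            (other, other),       # I006
            (other, other),       # I007
        ]
        cohort, marker_map = make_cohort_from_haps(rows, spacing=40_000)
        # markers at 40k..480k; focal at 260k center
        focal = FocalVariant("1", 260_000, ["I000", "I001"])
        res_small = define_carrier_haplotype(cohort, marker_map, focal, 400_000)
        hits_small = {m.individual_id for m in scan_cohort(cohort, marker_map, res_small)}
        assert hits_small == {"I002", "I003", "I004"}
        res_large = define_carrier_haplotype(cohort, marker_map, focal, 880_000)
        hits_large = {m.individual_id for m in scan_cohort(cohort, marker_map, res_large)}
        assert hits_large == {"I002", "I003"}
        # brute-force string comparison agrees
        idx = res_large.candidates[0].marker_indices
        pairs = [cohort.alleles[i][idx].tolist() for i in range(8)]
        strings = {tuple(c.alleles.tolist()) for c in res_large.candidates}
        assert brute_scan(pairs, list(cohort.ids), strings, {"I000", "I001"}) == hits_large

    def test_iid_cohort_match_count_near_product_formula(self):
        # expected matches: per individual 1 - (1 - prod p_match)^2 under
        # i.i.d. markers; averaged over 30 seeds
        n, m = 40, 12
        observed, expected = 0.0, 0.0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            freqs = rng.uniform(0.2, 0.8, m)
            alleles = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
            cohort, marker_map = make_random_cohort(n, m, rng)
            cohort.alleles[:] = alleles
            focal = FocalVariant("1", 60_000, ["I000"])
            result = define_carrier_haplotype(cohort, marker_map, focal, 240_000)
            idx = result.candidates[0].marker_indices
            hits = scan_cohort(cohort, marker_map, result)
            observed += len(hits)
            # candidates are the single carrier's (distinct) haplotypes, so a
            # random haplotype matches with probability sum of the per-string
            # products (the strings are mutually exclusive matches)
            strings = [c.alleles for c in result.candidates]
            p_hap = sum(
                float(np.prod(np.where(s == 1, freqs[idx], 1 - freqs[idx])))
                for s in strings
            )
            expected += (n - 1) * (1 - (1 - p_hap) ** 2)
        assert observed == pytest.approx(expected, rel=0.25, abs=10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_define_and_scan_agree_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        m = int(rng.integers(10, 120))
        cohort, marker_map = make_random_cohort(n, m, rng, missing_rate=0.03)
        n_carriers = int(rng.integers(1, 4))
        carriers = [f"I{i:03d}" for i in rng.choice(n, n_carriers, replace=False)]
        focal_pos = int(rng.integers(1, m * 10_000))
        window = int(rng.integers(30_000, m * 10_000))
        focal = FocalVariant("1", focal_pos, carriers)
        try:
            result = define_carrier_haplotype(cohort, marker_map, focal, window)
        except WindowError:
            return
        idx = marker_map.window_indices(
            "1", focal_pos - window // 2, focal_pos - window // 2 + window
        )
        order = _scan_order(marker_map.pos[idx], focal_pos)
        pairs = [cohort.alleles[cohort.index_of(c)][idx].tolist() for c in carriers]
        status, strings = brute_define(pairs, order)
        assert result.status == status
        if result.ok:
            assert {tuple(c.alleles.tolist()) for c in result.candidates} == strings
            all_pairs = [cohort.alleles[i][idx].tolist() for i in range(n)]
            hits = {m_.individual_id for m_ in scan_cohort(cohort, marker_map, result)}
            assert hits == brute_scan(all_pairs, list(cohort.ids), strings, set(carriers))


class TestSweep:
    def _planted_sim(self, seed):
        config = SimConfig(
            genome=[("1", 20_000_000)],
            cm_per_mb=0.5,
            founder_maf_min=0.3,
            pedigree_spec=PedigreeSpec(
                [KindredSpec(3, 3.0), KindredSpec(3, 3.0)],
                n_unrecorded_links=2,
                link_meioses_per_side=1,
                shared_ancestor=True,
            ),
            seed=seed,
        )
        return simulate_cohort(
            config, founder_hap_label="link",
            require_carrier_kindreds=2, require_known_kindred_carriers=2,
            min_flank_mb=1.0,
        )

    def test_carriers_only_cohort_gives_empty_match_sets(self):
        sim = self._planted_sim(31)
        carriers = sim.recorded_carrier_ids
        sub = sim.cohort.subset_individuals(carriers)
        focal = sim.variant.as_focal(carriers)
        sweep = coarse_sweep(sub, sim.marker_map, focal,
                             increment_bp=200_000, max_length_bp=2_000_000)
        for row in sweep.rows:
            assert row.match_ids == []

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_nestedness_and_oracle_per_window(self, seed):
        sim = self._planted_sim(seed)
        by_kindred = sim.carriers_by_kindred()
        best = max(by_kindred, key=lambda k: len(by_kindred[k]))
        known = sorted(by_kindred[best])[:3]
        focal = sim.variant.as_focal(known)
        sweep = coarse_sweep(sim.cohort, sim.marker_map, focal,
                             increment_bp=200_000, max_length_bp=3_000_000)
        sweep.verify_nested()
        assert sweep.rows
        for row in sweep.rows[:4]:
            idx = row.consensus.candidates[0].marker_indices
            strings = {tuple(c.alleles.tolist()) for c in row.consensus.candidates}
            pairs = [sim.cohort.alleles[i][idx].tolist()
                     for i in range(sim.cohort.n_individuals)]
            assert set(row.match_ids) == brute_scan(
                pairs, list(sim.cohort.ids), strings, set(known)
            )


class TestFineExtend:
    def test_identical_haplotypes_span_whole_chromosome(self, rng):
        cohort, marker_map = make_random_cohort(2, 50, rng)
        hap = cohort.alleles[0, :, 0]
        iv = fine_extend(hap, hap.copy(), marker_map, "1", 250_000)
        assert not iv.empty
        assert iv.start_bp == marker_map.pos[0]
        assert iv.end_bp == marker_map.pos[-1]
        assert iv.n_matching_markers == 50

    def test_twelve_marker_toy_interval(self):
        # markers at 10k..120k; focal between markers 6 and 7 (65 kb);
        # mismatches at marker index 1 (left) and 10 (right)
        a = np.ones(12, dtype=np.int8)
        b = np.ones(12, dtype=np.int8)
        b[1] = 0
        b[10] = 0
        _, marker_map = make_random_cohort(1, 12, np.random.default_rng(0))
        iv = fine_extend(a, b, marker_map, "1", 65_000)
        assert (iv.start_bp, iv.end_bp) == (30_000, 100_000)
        assert iv.n_matching_markers == 8
        oracle = brute_fine(a.tolist(), b.tolist(), marker_map.pos.tolist(), 65_000)
        assert oracle == (30_000, 100_000, 8)
        # outer bound spans the mismatching flanks
        assert (iv.outer_start_bp, iv.outer_end_bp) == (20_000, 110_000)

    def test_mismatch_in_four_closest_gives_empty(self, rng):
        a = np.ones(12, dtype=np.int8)
        b = np.ones(12, dtype=np.int8)
        b[6] = 0  # adjacent to the focal point
        _, marker_map = make_random_cohort(1, 12, rng)
        iv = fine_extend(a, b, marker_map, "1", 65_000)
        assert iv.empty and iv.length_bp == 0

    def test_focal_outside_map_is_error(self, rng):
        cohort, marker_map = make_random_cohort(2, 10, rng)
        with pytest.raises(ValidationError):
            fine_extend(cohort.alleles[0, :, 0], cohort.alleles[1, :, 0],
                        marker_map, "1", 5_000_000)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_per_side_oracle(self, seed):
        rng = np.random.default_rng(seed + 500)
        m = int(rng.integers(8, 200))
        cohort, marker_map = make_random_cohort(2, m, rng, missing_rate=0.05)
        a = cohort.alleles[0, :, 0]
        b = cohort.alleles[1, :, 1]
        focal = int(rng.integers(10_000, m * 10_000))
        oracle = brute_fine(a.tolist(), b.tolist(), marker_map.pos.tolist(), focal)
        iv = fine_extend(a, b, marker_map, "1", focal)
        if oracle is None:
            assert iv.empty
        else:
            assert (iv.start_bp, iv.end_bp, iv.n_matching_markers) == oracle


class TestBackgroundFrequency:
    def test_zero_resolved_markers_matches_everything(self, rng):
        cohort, marker_map = make_random_cohort(6, 10, rng)
        cohort.alleles[:3, 4:6, :] = MISSING  # carriers all-missing in window
        focal = FocalVariant("1", 50_000, ["I000", "I001", "I002"])
        result = define_carrier_haplotype(cohort, marker_map, focal,
                                          window=(45_000, 65_000),
                                          window_length_bp=20_000)
        assert result.candidates[0].n_resolved == 0
        assert haplotype_background_frequency(cohort, result) == 1.0

    def test_unique_planted_haplotype_has_zero_background(self):
        config = SimConfig(
            genome=[("1", 20_000_000)],
            pedigree_spec=PedigreeSpec([KindredSpec(3, 3.0)]),
            founder_maf_min=0.3,
            seed=77,
        )
        sim = simulate_cohort(config, founder_hap_label=0,
                              require_known_kindred_carriers=2, min_flank_mb=2.0)
        carriers = sim.recorded_carrier_ids
        focal = sim.variant.as_focal(carriers[:3])
        result = define_carrier_haplotype(sim.cohort, sim.marker_map, focal, 3_000_000)
        if result.ok:
            freq = haplotype_background_frequency(sim.cohort, result, carriers)
            assert freq == 0.0

    def test_iid_cohort_frequency_near_product(self):
        n, m = 300, 10
        rng = np.random.default_rng(9)
        freqs = rng.uniform(0.3, 0.7, m)
        alleles = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
        cohort, marker_map = make_random_cohort(n, m, rng)
        cohort.alleles[:] = alleles
        consensus = (rng.random(m) < freqs).astype(np.int8)
        from haploscan.haplotype_scan import CarrierHaplotype

        cand = CarrierHaplotype("1", 0, m * 10_000 + 1, np.arange(m),
                                consensus, [], {})
        observed = haplotype_background_frequency(cohort, cand, [])
        expected = float(np.prod(np.where(consensus == 1, freqs, 1 - freqs)))
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert abs(observed - expected) < 4 * se + 1e-9
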