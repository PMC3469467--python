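"""Forward-simulator behavior: meiosis draws, marker observation, RAIL
propagation, and reproducibility."""

import numpy as np
import pytest

from recland import (ChromosomeSpec, CrossDesign, GCParams, MarkerPanel,
                     detect_events, make_marker_panel, observe_haplotypes,
                     simulate_meiosis, simulate_rail)
from recland.designs import bottle_schedule
from recland.detect import estimate_equivalent_meioses
from recland.simulate import Haplotype, _meiosis_arm


def small_design(n_generations, chroms, offspring=200):
    return CrossDesign(
        cross_id="t", n_generations=n_generations,
        n_bottles_schedule=bottle_schedule(n_generations, 2, 3),
        chromosomes=chroms, males_per_bottle=10, females_per_bottle=10,
        offspring_sampled=offspring)


class TestMeiosis:
    def test_zero_gc_rate_yields_no_tracts(self, small_arm, rng):
        gc0 = GCParams(gamma=0.0, phi=0.0)
        for _ in range(50):
            truth = simulate_meiosis(small_arm, gc0, rng)
            assert truth.gc_tracts == []

    def test_co_count_poisson_expectation(self, default_gc, rng):
        chrom = ChromosomeSpec("a", 1_000_000, map_length_cM=50.0)
        counts = [simulate_meiosis(chrom, GCParams(0, 0), rng).co_positions.size
                  for _ in range(20_000)]
        counts = np.asarray(counts)
        se = counts.std() / np.sqrt(counts.size)
        assert abs(counts.mean() - 0.5) < 3 * se
        # no-interference Poisson: variance matches the mean
        assert abs(counts.var() - counts.mean()) < 5 * se

    def test_geometric_tract_mean_matches_closed_form(self, rng):
        phi = 1.0 - 1.0 / 518.0
        draws = rng.geometric(1 - phi, size=100_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 518.0) < 3 * se

    def test_rejects_invalid_model_parameters(self):
        with pytest.raises(ValueError):
            GCParams(gamma=-1e-8, phi=0.5)
        with pytest.raises(ValueError):
            GCParams(gamma=1e-8, phi=1.0)
        with pytest.raises(ValueError):
            ChromosomeSpec("a", 1000, map_length_cM=-1.0)

    def test_event_counts_match_requested_initiations(self, default_gc, rng):
        """Truth records exactly the drawn CO + GC initiations per gamete."""
        chrom = ChromosomeSpec("a", 200_000, map_length_cM=80.0)
        hot = GCParams.from_mean_length(gamma=3e-5, l_gc=100.0)
        n_co = n_gc = 0
        for _ in range(200):
            truth = simulate_meiosis(chrom, hot, rng)
            n_co += truth.co_positions.size
            n_gc += len(truth.gc_tracts)
        # Poisson expectations: 0.8 CO and 6 GC per gamete
        assert abs(n_co / 200 - 0.8) < 0.2
        assert abs(n_gc / 200 - 6.0) < 0.6

    def test_uniform_co_positions_pass_ks(self, rng):
        from scipy import stats
        chrom = ChromosomeSpec("a", 10_000_000, map_length_cM=50.0)
        pos = np.concatenate([
            simulate_meiosis(chrom, GCParams(0, 0), rng,
                             co_count_mode="fixed", fixed_co_count=5).co_positions
            for _ in range(20_000)])
        assert pos.size == 100_000
        p = stats.kstest(pos / chrom.length_bp, "uniform").pvalue
        assert p > 0.001

    def test_co_landscape_shifts_positions(self, rng):
        land = np.array([0.0, 0.0, 1.0, 1.0])  # CO only in the right half
        chrom = ChromosomeSpec("a", 1_000_000, map_length_cM=100.0,
                               co_landscape=land)
        pos = np.concatenate([
            simulate_meiosis(chrom, GCParams(0, 0), rng).co_positions
            for _ in range(2_000)])
        assert pos.min() >= 500_000

    def test_seeded_runs_bit_reproducible(self, small_arm, default_gc):
        t1 = simulate_meiosis(small_arm, default_gc, 123)
        t2 = simulate_meiosis(small_arm, default_gc, 123)
        np.testing.assert_array_equal(t1.seg_starts, t2.seg_starts)
        np.testing.assert_array_equal(t1.seg_parents, t2.seg_parents)
        np.testing.assert_array_equal(t1.co_positions, t2.co_positions)
        assert t1.gc_tracts == t2.gc_tracts


class TestObserve:
    def test_tract_between_markers_is_invisible(self):
        from recland.core import SimTruth
        truth = SimTruth(arm_id="a", length_bp=10_000,
                         seg_starts=[0, 4_100, 4_400],
                         seg_parents=[0, 1, 0],
                         co_positions=[], gc_tracts=[(4_100, 300, 1)])
        panel = MarkerPanel("a", np.array([3_000, 5_000, 7_000]))
        hap = observe_haplotypes(truth, panel)
        assert np.all(hap.parents == 0)
        assert detect_events(hap) == []

    def test_single_co_yields_one_persistent_switch(self):
        from recland.core import SimTruth
        truth = SimTruth(arm_id="a", length_bp=10_000,
                         seg_starts=[0, 4_500], seg_parents=[0, 1],
                         co_positions=[4_500], gc_tracts=[])
        panel = MarkerPanel("a", np.arange(500, 10_000, 1_000))
        hap = observe_haplotypes(truth, panel)
        switches = np.flatnonzero(np.diff(hap.parents))
        assert switches.size == 1
        events = detect_events(hap)
        assert [e.kind for e in events] == ["CO"]
        assert (events[0].left_flank_pos, events[0].right_flank_pos) == (3_500, 4_500)

    def test_marker_calls_match_covering_segments(self, small_arm, default_gc, rng):
        """Conservation: every observed call equals the truth segment parent."""
        panel = make_marker_panel(small_arm.arm_id, small_arm.length_bp, 500, rng)
        for _ in range(20):
            truth = simulate_meiosis(small_arm, default_gc, rng)
            hap = observe_haplotypes(truth, panel)
            for pos, par in zip(hap.positions[::37], hap.parents[::37]):
                seg = np.searchsorted(truth.seg_starts, pos, side="right") - 1
                assert truth.seg_parents[seg] == par

    def test_empty_panel_rejected(self, small_arm, default_gc):
        truth = simulate_meiosis(small_arm, default_gc, 0)
        with pytest.raises(ValueError):
            observe_haplotypes(truth, MarkerPanel("2L", np.array([], dtype=int)))

    def test_detected_gc_deficit_grows_with_marker_spacing(self, default_gc, rng):
        chrom = ChromosomeSpec("a", 1_000_000, map_length_cM=0.0, has_co=False)
        hot = GCParams.from_mean_length(gamma=2e-6, l_gc=518.0)
        panels = {sp: MarkerPanel("a", np.arange(sp, 1_000_000, sp))
                  for sp in (2_000, 10_000)}
        detected = {sp: 0 for sp in panels}
        true_total = 0
        for _ in range(2_000):
            truth = simulate_meiosis(chrom, hot, rng)
            true_total += len(truth.gc_tracts)
            for sp, panel in panels.items():
                evs = detect_events(observe_haplotypes(truth, panel))
                detected[sp] += sum(1 for e in evs if e.kind == "GC")
        assert detected[2_000] <= true_total
        assert detected[10_000] < detected[2_000]

    def test_dense_panel_recovers_truth_counts(self, default_gc, rng):
        """Round-trip: at 200-bp spacing detected counts approach the truth."""
        chrom = ChromosomeSpec("a", 1_000_000, map_length_cM=20.0)
        panel = MarkerPanel("a", np.arange(100, 1_000_000, 200))
        true_co = true_gc = det_co = det_gc = 0
        for _ in range(2_000):
            truth = simulate_meiosis(chrom, default_gc, rng)
            true_co += truth.co_positions.size
            true_gc += len(truth.gc_tracts)
            evs = detect_events(observe_haplotypes(truth, panel))
            det_co += sum(1 for e in evs if e.kind == "CO")
            det_gc += sum(1 for e in evs if e.kind == "GC")
        assert abs(det_co - true_co) <= 0.02 * true_co
        assert det_gc <= true_gc
        assert det_gc >= 0.85 * true_gc  # tracts shorter than 200 bp can hide


class TestRail:
    def test_one_generation_equals_single_meiosis(self, default_gc, rng):
        chrom = ChromosomeSpec("a", 2_000_000, map_length_cM=60.0)
        design = small_design(1, [chrom], offspring=4_000)
        genomes = simulate_rail(design, default_gc, rng)
        mean_co = np.mean([g["a"].co_positions.size for g in genomes])
        se = np.sqrt(0.6 / len(genomes))
        assert abs(mean_co - 0.6) < 3.5 * se

    def test_detectable_co_nondecreasing_in_generations(self, rng):
        chrom = ChromosomeSpec("a", 2_000_000, map_length_cM=60.0)
        gc0 = GCParams(0, 0)
        means = []
        for gens in (1, 3, 5):
            design = small_design(gens, [chrom], offspring=2_500)
            genomes = []
            for _ in range(4):  # average over pedigrees to tame drift
                genomes += simulate_rail(design, gc0, rng, n_sampled=625)
            means.append(np.mean([g["a"].co_positions.size for g in genomes]))
        assert means[0] <= means[1] <= means[2]

    def test_x_and_mito_transmission(self, rng):
        chroms = [
            ChromosomeSpec("X", 1_000_000, map_length_cM=30.0, inheritance="X"),
            ChromosomeSpec("mt", 20_000, map_length_cM=0.0, has_co=False,
                           inheritance="mito"),
        ]
        design = small_design(3, chroms, offspring=50)
        genomes = simulate_rail(design, GCParams(0, 0), rng)
        for g in genomes:
            # mitochondria are clonal: single founder segment, no events
            assert g["mt"].seg_starts.size == 1
            assert g["mt"].co_positions.size == 0
            assert g["X"].length_bp == 1_000_000

    def test_dot_chromosome_gets_gc_but_no_co(self, rng):
        dot = ChromosomeSpec("4", 1_300_000, map_length_cM=0.0, has_co=False)
        hot = GCParams.from_mean_length(gamma=2e-6, l_gc=518.0)
        design = small_design(2, [dot], offspring=300)
        genomes = simulate_rail(design, hot, rng)
        n_gc = sum(len(g["4"].gc_tracts) for g in genomes)
        assert all(g["4"].co_positions.size == 0 for g in genomes)
        assert n_gc > 0

    def test_extinct_design_errors(self):
        with pytest.raises(ValueError):
            CrossDesign(cross_id="bad", n_generations=2,
                        n_bottles_schedule=[0, 1],
                        chromosomes=[ChromosomeSpec("a", 1000, 0.0, has_co=False)])


class TestEquivalentMeioses:
    def test_single_generation_is_exactly_one(self):
        chrom = ChromosomeSpec("a", 2_000_000, map_length_cM=60.0)
        design = small_design(1, [chrom])
        assert estimate_equivalent_meioses(design, n_reps=100, rng=0) == 1.0

    def test_nondecreasing_in_generations(self):
        chrom = ChromosomeSpec("a", 2_000_000, map_length_cM=60.0)
        eqs = [estimate_equivalent_meioses(small_design(g, [chrom]),
                                           n_reps=2_000, rng=11)
               for g in (1, 3, 5)]
        assert eqs[0] <= eqs[1] <= eqs[2]
        assert eqs[2] > 1.2

    def test_self_consistent_map_recovery(self):
        """Two independent equivalent-meioses estimates agree within 2%,
        so normalizing simulated counts recovers the input map length."""
        chroms = [ChromosomeSpec("2L", 23_011_544, map_length_cM=55.8),
                  ChromosomeSpec("2R", 21_146_708, map_length_cM=53.8)]
        design = small_design(3, chroms, offspring=700)
        eq_a = estimate_equivalent_meioses(design, n_reps=10_000, rng=1,
                                           n_pedigrees=50)
        eq_b = estimate_equivalent_meioses(design, n_reps=10_000, rng=2,
                                           n_pedigrees=50)
        assert abs(eq_a - eq_b) / eq_a < 0.02


class TestMeiosisInternals:
    def test_gamete_is_mosaic_of_parent_haplotypes(self, rng):
        chrom = ChromosomeSpec("a", 100_000, map_length_cM=200.0)
        hapA = Haplotype([0, 40_000], [0, 1], junctions=[40_000])
        hapB = Haplotype([0], [1])
        gam = _meiosis_arm(hapA, hapB, chrom, GCParams(0, 0), rng)
        # every gamete position matches one of the two inputs
        xs = rng.integers(0, 100_000, size=200)
        ok = (gam.parent_at(xs) == hapA.parent_at(xs)) | \
             (gam.parent_at(xs) == hapB.parent_at(xs))
        assert np.all(ok)

    def test_homozygous_mother_transmits_no_events(self, rng):
        chrom = ChromosomeSpec("a", 500_000, map_length_cM=100.0)
        hap = Haplotype([0], [0])
        gam = _meiosis_arm(hap, Haplotype([0], [0]), chrom,
                           GCParams(1e-5, 0.99), rng)
        assert gam.junctions.size == 0
        assert gam.gc_tracts == []
        assert np.all(gam.parents == 0)
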