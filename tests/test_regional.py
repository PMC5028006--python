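"""Region tiling, word entropies, shuffle-corrected MI and IT."""

import numpy as np
import pytest
from scipy import stats

from neurocascade.core import Mask, PointProcessMovie
from neurocascade.regional import (
    RegionSymbolSequence,
    half_temporal_resolution,
    information_transmission,
    mi_matrix,
    mutual_information,
    region_patterns,
    regional_analysis,
    regional_entropy,
    resolution_variants,
    shuffle_corrected_mi,
    tile_regions,
)
from neurocascade.synthetic import SimulationConfig, simulate_branching_cascades

from oracles import entropy_oracle


def words(bits):
    return RegionSymbolSequence(0, np.asarray(bits, dtype=bool))


def seq_from_codes(codes, n_bits=4):
    """Distinct integer codes -> distinct binary words."""
    codes = np.asarray(codes)
    lut = np.array(
        [[(i >> b) & 1 for b in range(n_bits)] for i in range(2**n_bits)],
        dtype=bool,
    )
    return RegionSymbolSequence(0, lut[codes])


class TestTiling:
    def test_full_16x16_gives_four_8x8_regions(self):
        grid = tile_regions(Mask.full(16, 16), 8)
        assert grid.n_regions == 4
        assert grid.extent == pytest.approx(np.hypot(15, 15))

    def test_partial_row_dropped(self):
        grid = tile_regions(Mask.full(15, 16), 8)
        assert grid.n_regions == 2

    def test_hole_inside_tile_drops_it(self):
        include = np.ones((16, 16), dtype=bool)
        include[3, 3] = False
        grid = tile_regions(Mask(include), 8)
        assert grid.n_regions == 3
        assert all(r.origin != (0, 0) for r in grid.regions)

    def test_tiles_anchor_at_mask_bounding_box(self):
        include = np.zeros((20, 20), dtype=bool)
        include[5:13, 7:15] = True
        grid = tile_regions(Mask(include), 8)
        assert grid.n_regions == 1
        assert grid.regions[0].origin == (5, 7)

    def test_no_fitting_tile_rejected(self):
        with pytest.raises(ValueError, match="no complete"):
            tile_regions(Mask.full(4, 4), 8)


class TestPatterns:
    def test_silent_region_yields_single_zero_word(self):
        pp = PointProcessMovie(np.zeros((10, 8, 8), dtype=bool), 50.0)
        [seq] = region_patterns(pp, tile_regions(Mask.full(8, 8), 8))
        assert not seq.words.any()
        assert len(np.unique(seq.codes)) == 1

    def test_single_event_sets_row_major_bit(self):
        events = np.zeros((3, 8, 8), dtype=bool)
        events[1, 2, 5] = True
        [seq] = region_patterns(pp := PointProcessMovie(events, 50.0),
                                tile_regions(Mask.full(8, 8), 8))
        assert seq.words[1].sum() == 1
        assert seq.words[1][2 * 8 + 5]

    def test_total_set_bits_conserve_event_count(self, rng):
        events = rng.random((30, 16, 16)) < 0.1
        pp = PointProcessMovie(events, 50.0)
        grid = tile_regions(Mask.full(16, 16), 8)
        total = sum(s.words.sum() for s in region_patterns(pp, grid))
        assert total == events.sum()


class TestEntropyAndMI:
    def test_single_word_zero_entropy(self):
        assert regional_entropy(words([[0, 0], [0, 0]])) == 0.0

    def test_two_equiprobable_words_one_bit(self):
        assert regional_entropy(words([[0, 1], [1, 0]] * 5)) == pytest.approx(1.0)

    def test_matches_counting_oracle(self, rng):
        bits = rng.random((200, 6)) < 0.4
        seq = RegionSymbolSequence(0, bits)
        expected = entropy_oracle(map(tuple, bits.tolist()))
        assert regional_entropy(seq) == pytest.approx(expected)

    def test_mi_with_itself_is_entropy(self, rng):
        x = words(rng.random((100, 4)) < 0.5)
        assert mutual_information(x, x) == pytest.approx(regional_entropy(x))

    def test_independent_patterns_zero_mi(self):
        x = seq_from_codes([0, 0, 1, 1])
        y = seq_from_codes([2, 3, 2, 3])
        assert mutual_information(x, y) == pytest.approx(0.0)

    def test_perfect_coupling_one_bit(self):
        x = seq_from_codes([0, 0, 1, 1])
        y = seq_from_codes([2, 2, 3, 3])
        assert mutual_information(x, y) == pytest.approx(1.0)

    def test_symmetry_and_bounds(self, rng):
        x = words(rng.random((300, 4)) < 0.3)
        y = words(rng.random((300, 4)) < 0.3)
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mutual_information(y, x))
        assert 0.0 <= mi <= min(regional_entropy(x), regional_entropy(y))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            mutual_information(words(np.zeros((5, 2))), words(np.zeros((6, 2))))


class TestShuffleCorrection:
    def test_identical_sequences_retain_entropy(self, rng):
        x = words(rng.random((5000, 4)) < 0.5)
        corrected, raw, control = shuffle_corrected_mi(x, x, n_shuffles=10, seed=0)
        h = regional_entropy(x)
        assert raw == pytest.approx(h)
        assert control < 0.1 * h
        assert corrected == pytest.approx(h, rel=0.05)

    def test_independent_sequences_corrected_near_zero(self, rng):
        """Mean corrected MI over 20 seeds is within 3 s.e. of zero."""
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = words(r.random((2000, 3)) < 0.4)
            y = words(r.random((2000, 3)) < 0.4)
            corrected, _, _ = shuffle_corrected_mi(x, y, n_shuffles=10, seed=seed)
            vals.append(corrected)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-4

    def test_control_converges_with_more_shuffles(self, rng):
        x = words(rng.random((1500, 3)) < 0.4)
        y = words(rng.random((1500, 3)) < 0.4)
        controls = {
            n: np.std([
                shuffle_corrected_mi(x, y, n_shuffles=n, seed=s)[2]
                for s in range(8)
            ])
            for n in (1, 20)
        }
        assert controls[20] < controls[1]

    def test_shuffle_count_validated(self, rng):
        x = words(rng.random((10, 2)) < 0.5)
        with pytest.raises(ValueError):
            shuffle_corrected_mi(x, x, n_shuffles=0)


class TestInformationTransmission:
    def _two_coupled_distant_regions(self):
        """32x8 mask -> four 8x8 regions; first and last perfectly coupled."""
        rng = np.random.default_rng(0)
        events = np.zeros((800, 32, 8), dtype=bool)
        driver = rng.random(800) < 0.5
        events[driver, 1, 1] = True    # region 0
        events[driver, 25, 1] = True   # region 3, identical timing
        pp = PointProcessMovie(events, 50.0)
        grid = tile_regions(Mask.full(32, 8), 8)
        patterns = region_patterns(pp, grid)
        return grid, patterns

    def test_distant_coupled_regions_dominate_it(self):
        grid, patterns = self._two_coupled_distant_regions()
        mim = mi_matrix(patterns, n_shuffles=5, seed=1)
        it = information_transmission(mim, grid, exclusion_fraction=0.1)
        h = regional_entropy(patterns[0])
        assert it[0] == pytest.approx(h, rel=0.1)
        assert it[3] == pytest.approx(h, rel=0.1)
        assert max(abs(it[1]), abs(it[2])) < 0.1 * h

    def test_all_pairs_excluded_gives_zero_it(self):
        grid, patterns = self._two_coupled_distant_regions()
        mim = mi_matrix(patterns, n_shuffles=5, seed=1)
        it = information_transmission(mim, grid, exclusion_fraction=2.0)
        assert np.allclose(it, 0.0)
        assert mim.excluded.all()

    def test_total_it_twice_the_included_pair_sum(self, rng):
        events = rng.random((200, 16, 16)) < 0.08
        res = regional_analysis(PointProcessMovie(events, 50.0), region_size=8,
                                n_shuffles=3, seed=2)
        mim = res["mi"]
        included_sum = mim.corrected[~mim.excluded].sum()
        assert res["it"].sum() == pytest.approx(included_sum)

    def test_higher_entropy_regions_transmit_more_on_critical_sim(self):
        """Across regions of a critical simulation, H_reg and IT are
        positively rank-correlated, and per-region κ centres near 1."""
        from neurocascade.cascades import regional_kappa

        cfg = SimulationConfig(32, 32, 3000, branching_param=1.0,
                               drive_rate=7e-4, seed=9)
        pp, _, _ = simulate_branching_cascades(cfg)
        res = regional_analysis(pp, seed=3)
        rho = stats.spearmanr(res["h_reg"], res["it"]).statistic
        assert rho > 0
        kreg = np.array(
            [v["kappa"] for v in regional_kappa(pp, res["grid"]).values()]
        )
        assert abs(np.nanmean(kreg) - 1.0) < 0.15


class TestResolutionVariants:
    def test_variant_b_equals_default_analysis(self, rng):
        events = rng.random((200, 16, 16)) < 0.08
        pp = PointProcessMovie(events, 50.0)
        default = regional_analysis(pp, region_size=8, n_shuffles=3, seed=5)
        out = resolution_variants(pp, n_shuffles=3, seed=5, variants="b")
        assert np.allclose(out["b"]["h_reg"], default["h_reg"])
        assert np.allclose(out["b"]["it"], default["it"])

    def test_half_temporal_halves_length_with_or_rule(self):
        events = np.zeros((6, 2, 2), dtype=bool)
        events[0, 0, 0] = events[1, 1, 1] = True
        half = half_temporal_resolution(PointProcessMovie(events, 50.0))
        assert half.n_frames == 3
        assert half.frame_rate == 25.0
        assert half.events[0, 0, 0] and half.events[0, 1, 1]

    def test_entropy_structure_consistent_across_variants(self):
        """Regional entropy rankings agree between 5x5 and 8x8 tilings of a
        critical simulation (region centres matched by nearest distance)."""
        cfg = SimulationConfig(24, 24, 2000, branching_param=1.0,
                               drive_rate=7e-4, seed=21)
        pp, _, _ = simulate_branching_cascades(cfg)
        out = resolution_variants(pp, n_shuffles=3, seed=6, variants="ab")
        grid_a, grid_b = out["a"]["grid"], out["b"]["grid"]
        centers_a, centers_b = grid_a.centers(), grid_b.centers()
        nearest = [
            int(np.argmin(np.linalg.norm(centers_a - c, axis=1)))
            for c in centers_b
        ]
        h_a = np.asarray(out["a"]["h_reg"])[nearest]
        h_b = np.asarray(out["b"]["h_reg"])
        rho = stats.spearmanr(h_a, h_b).statistic
        assert rho > 0
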