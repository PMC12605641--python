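"""Artifact-severity scoring, tiling, and the counting-evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdecon.hass_bench import (
    HassTile,
    TileGrid,
    bland_altman,
    counting_errors,
    hass_terms,
    paired_wilcoxon_holm,
    score_slide,
    significance_threshold,
    stratify_hass,
    tile_roi,
)
from segdecon.image_pp import rgb_to_hsv
from segdecon.synthetic import SynthImageSpec, synth_hne


class TestTileRoi:
    def test_origin_point(self):
        counts = tile_roi(TileGrid(), [(0, 0)])
        assert counts[(0, 0)] == 1

    def test_half_open_boundary(self):
        counts = tile_roi(TileGrid(), [(500, 499)])
        assert counts[(0, 1)] == 1

    def test_default_grid_has_36_tiles(self):
        assert TileGrid().n_tiles == 36
        assert len(tile_roi(TileGrid(), [])) == 36

    def test_outside_points_dropped(self):
        counts = tile_roi(TileGrid(), [(-1, 0), (3000, 10), (10, 10)])
        assert sum(counts.values()) == 1

    def test_inconsistent_grid_rejected(self):
        with pytest.raises(ValueError):
            TileGrid(roi_size=3000, grid=5, tile_size=500)


def tile_pair(frac_lo=0.02, frac_hi=0.10, seed=0):
    """Two tiles identical in construction except for speckle burden."""
    out = []
    for frac in (frac_lo, frac_hi):
        res = synth_hne(
            SynthImageSpec(size_px=192, n_nuclei=16, speckle_fraction=frac),
            seed=seed,
        )
        hsv = rgb_to_hsv(res.rgb)
        out.append(
            hass_terms(hsv.v, res.speckle_mask, res.nuclei_mask)
        )
    return out


class TestHass:
    def test_artifact_free_tile_scores_zero(self, clean_tile):
        hsv = rgb_to_hsv(clean_tile.rgb)
        terms = hass_terms(hsv.v, np.zeros(hsv.shape, bool), clean_tile.nuclei_mask)
        assert all(v == 0.0 for v in terms.values())

    def test_speckle_fraction_term_monotone(self):
        lo, hi = tile_pair()
        assert hi["speckle_area_fraction"] > lo["speckle_area_fraction"]

    @pytest.mark.parametrize("seed", range(8))
    def test_composite_monotone_in_speckle_burden(self, seed):
        lo, hi = tile_pair(seed=seed)
        tiles = [HassTile((0, 0), lo), HassTile((0, 1), hi)]
        score_slide(tiles)
        assert tiles[1].score > tiles[0].score

    def test_all_terms_bounded(self, speckled_tile):
        hsv = rgb_to_hsv(speckled_tile.rgb)
        terms = hass_terms(
            hsv.v, speckled_tile.speckle_mask, speckled_tile.nuclei_mask
        )
        assert all(0.0 <= v <= 1.0 for v in terms.values())


class TestStratify:
    def test_all_equal_scores_all_level_one(self):
        assert stratify_hass(np.full(36, 0.5)).tolist() == [1] * 36

    def test_matches_sorted_partition_oracle(self):
        scores = np.concatenate([np.arange(1, 36), [17.0]])
        levels = stratify_hass(scores)
        # oracle: quintile boundaries of the empirical distribution,
        # ties to the lower level
        qs = np.percentile(scores, [20, 40, 60, 80])
        want = np.array([1 + (s > qs).sum() for s in scores])
        assert np.array_equal(levels, want)
        # the duplicated score shares its level
        assert levels[-1] == levels[np.where(scores == 17.0)[0][0]]

    def test_balanced_split_of_36_distinct(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 36))
        levels = stratify_hass(scores)
        counts = np.bincount(levels)[1:]
        assert counts.max() - counts.min() <= 1
        assert set(levels) == {1, 2, 3, 4, 5}

    def test_exhaustive_partition(self, rng):
        scores = rng.uniform(0, 1, 77)
        levels = stratify_hass(scores)
        assert ((levels >= 1) & (levels <= 5)).all()


class TestCountingMetrics:
    def test_perfect_prediction(self):
        assert counting_errors([3, 4], [3, 4]) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        me, mae, rmse = counting_errors([10, 20], [12, 16])
        assert me == pytest.approx(1.0)
        assert mae == pytest.approx(3.0)
        assert rmse == pytest.approx(np.sqrt(10))

    def test_symmetry_properties(self, rng):
        p = rng.integers(0, 50, 20)
        g = rng.integers(0, 50, 20)
        me, mae, _ = counting_errors(p, g)
        me2, mae2, _ = counting_errors(g, p)
        assert me2 == pytest.approx(-me)
        assert mae2 == pytest.approx(mae)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_rmse_mae_me_ordering(self, a, b):
        n = min(len(a), len(b))
        me, mae, rmse = counting_errors(a[:n], b[:n])
        assert rmse >= mae - 1e-9
        assert mae >= abs(me) - 1e-9


class TestBlandAltman:
    def test_identical_vectors(self):
        assert bland_altman([3, 5], [3, 5]) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        bias, lo, hi = bland_altman([12, 18], [10, 20])
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(8))
        assert hi == pytest.approx(5.5437, abs=1e-3)
        assert lo == pytest.approx(-hi)

    def test_translation_equivariance(self, rng):
        p = rng.uniform(0, 50, 15)
        g = rng.uniform(0, 50, 15)
        bias, lo, hi = bland_altman(p, g)
        bias2, lo2, hi2 = bland_altman(p + 7.5, g)
        assert bias2 == pytest.approx(bias + 7.5)
        assert lo2 == pytest.approx(lo + 7.5)
        assert hi2 == pytest.approx(hi + 7.5)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            bland_altman([1], [2])

    def test_loa_bracket_bias(self, rng):
        p = rng.uniform(0, 50, 15)
        g = rng.uniform(0, 50, 15)
        bias, lo, hi = bland_altman(p, g)
        assert lo <= bias <= hi


def holm_oracle(ps):
    """Step-down Holm by direct definition with max-accumulation."""
    ps = np.asarray(ps, float)
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestWilcoxonHolm:
    def test_single_comparison_unadjusted(self, rng):
        a = rng.uniform(0, 1, 12)
        b = a + rng.normal(1, 0.1, 12)
        raw, adj, _ = paired_wilcoxon_holm(a, b)
        assert adj[0] == pytest.approx(raw[0])

    def test_holm_worked_examples(self):
        assert np.allclose(holm_oracle([0.01, 0.04]), [0.02, 0.04])
        assert np.allclose(holm_oracle([0.03, 0.03, 0.03]), [0.09, 0.09, 0.09])
        from statsmodels.stats.multitest import multipletests

        for ps in ([0.01, 0.04], [0.03, 0.03, 0.03]):
            _, got, _, _ = multipletests(ps, method="holm")
            assert np.allclose(got, holm_oracle(ps))

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None)
    def test_holm_matches_bruteforce_oracle(self, ps):
        from statsmodels.stats.multitest import multipletests

        _, got, _, _ = multipletests(ps, method="holm")
        assert np.allclose(got, holm_oracle(ps), atol=1e-12)

    def test_all_zero_differences_give_p_one(self):
        a = np.array([3.0, 4.0, 5.0])
        raw, adj, _ = paired_wilcoxon_holm(a, a)
        assert raw[0] == 1.0 and adj[0] == 1.0

    def test_stratified_one_test_per_level(self, rng):
        a = rng.uniform(0, 1, 30)
        b = a + rng.normal(0.5, 0.2, 30)
        strata = np.repeat([1, 2, 3], 10)
        raw, adj, labels = paired_wilcoxon_holm(a, b, strata)
        assert len(raw) == len(adj) == len(labels) == 3
        assert np.all(adj >= raw - 1e-12)


class TestSignificanceThreshold:
    def test_no_shift_gives_none(self):
        levels = np.tile([1, 2, 3, 4, 5], 8)
        assert significance_threshold(np.zeros(40), levels) is None

    def test_matches_bruteforce_oracle_on_shifted_levels(self, rng):
        from scipy.stats import mannwhitneyu

        levels = np.tile([1, 2, 3, 4, 5], 8)
        delta = np.where(levels >= 3, rng.normal(20, 1, 40), rng.normal(0, 1, 40))
        want = None
        for L in (2, 3, 4, 5):
            hi, lo = delta[levels >= L], delta[levels < L]
            if hi.size and lo.size:
                if mannwhitneyu(hi, lo, alternative="two-sided").pvalue < 0.05:
                    want = L
                    break
        got = significance_threshold(delta, levels)
        assert got == want
        assert got is not None   # a clear shift is detected at some level

    def test_degenerate_single_level(self):
        assert significance_threshold(np.arange(10.0), np.full(10, 5)) is None
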