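"""Canopy metric computations: percentiles, energy accounting, waveforms."""

import numpy as np
import pytest

from firecarb.lidar import (EmptyTileError, MissingRangeError, METRIC_NAMES,
                            PointCloudTile, all_metrics, build_pseudowaveform,
                            height_metrics, intensity_metrics,
                            normalize_intensity, rasterize_metrics,
                            waveform_metrics)

from conftest import random_tile


def tile(heights, intensity=None, **kw):
    heights = np.asarray(heights, dtype=float)
    if intensity is None:
        intensity = np.ones_like(heights)
    return PointCloudTile(height_m=heights, intensity=np.asarray(intensity, float),
                          **kw)


class TestNormalizeIntensity:
    def test_identity_at_reference_and_inverse_square(self):
        t = tile([5.0, 5.0], intensity=[100.0, 100.0])
        t.range_m = np.array([1000.0, 2000.0])
        out = normalize_intensity(t, reference_range_m=1000.0)
        assert out.intensity[0] == pytest.approx(100.0)
        assert out.intensity[1] == pytest.approx(400.0)
        assert out.intensity_normalized

    def test_rank_order_preserved_at_equal_range(self, rng):
        t = random_tile(rng)
        t.range_m = np.full(t.n_returns, 900.0)
        out = normalize_intensity(t, reference_range_m=1234.0)
        assert np.array_equal(np.argsort(out.intensity, kind="stable"),
                              np.argsort(t.intensity, kind="stable"))

    def test_missing_range_signalled(self):
        t = tile([1.0], intensity=[5.0])
        with pytest.raises(MissingRangeError):
            normalize_intensity(t)


class TestHeightMetrics:
    def test_odd_count_median_and_depth(self):
        m = height_metrics(tile([3, 4, 5, 6, 7]))
        assert m["H50"] == pytest.approx(5.0)
        assert m["canopy_depth"] == pytest.approx(4.0)
        assert m["cover_ratio"] == pytest.approx(1.0)

    def test_cover_ratio_counts_all_returns(self):
        heights = [0.1] * 6 + [3.0, 4.0, 5.0, 6.0]
        m = height_metrics(tile(heights))
        assert m["cover_ratio"] == pytest.approx(0.4)

    def test_no_canopy_returns_yield_zero_stats(self):
        m = height_metrics(tile([0.0, 0.5, 1.0]))
        assert m["H50"] == 0.0 and m["mean_h"] == 0.0
        assert m["cover_ratio"] == 0.0

    def test_empty_tile_signalled(self):
        with pytest.raises(EmptyTileError):
            height_metrics(tile([]))

    def test_percentile_chain_monotone_on_random_tiles(self, rng):
        for _ in range(300):
            t = random_tile(rng)
            m = height_metrics(t)
            chain = [m[k] for k in ("H25", "H50", "H75", "H90", "H99")]
            assert all(a <= b + 1e-12 for a, b in zip(chain, chain[1:]))


class TestIntensityMetrics:
    def test_energy_cover_half_canopy(self):
        heights = [1.0] * 5 + [5.0] * 5
        m = intensity_metrics(tile(heights))
        assert m["FC_energy"] == pytest.approx(0.5)

    def test_accumulated_intensity_is_bounded_cumulative(self, rng):
        for _ in range(100):
            t = random_tile(rng)
            m = intensity_metrics(t)
            ai = [m[k] for k in ("AI_H25", "AI_H50", "AI_H75", "AI_H90", "AI_H99")]
            assert all(a <= b + 1e-12 for a, b in zip(ai, ai[1:]))
            assert ai[-1] <= 1.0 + 1e-12

    def test_dwcrs_invariant_under_return_duplication(self):
        t = tile([3, 5, 1], intensity=[2.0, 4.0, 1.0])
        m1 = intensity_metrics(t)
        t2 = tile([3, 5, 1, 3, 5, 1], intensity=[2, 4, 1, 2, 4, 1])
        m2 = intensity_metrics(t2)
        assert m2["CRS"] == pytest.approx(2 * m1["CRS"])
        assert m2["dwCRS"] == pytest.approx(m1["dwCRS"])

    def test_zero_intensity_gives_zero_ratios(self):
        m = intensity_metrics(tile([3.0, 0.1], intensity=[0.0, 0.0]))
        assert m["FC_energy"] == 0.0 and m["dwCRS"] == 0.0


class TestPseudowaveform:
    def test_single_return_single_bin(self):
        wf = build_pseudowaveform(tile([3.2], intensity=[5.0]))
        assert wf.total_energy == pytest.approx(5.0)
        assert np.count_nonzero(wf.amplitude) == 1

    def test_energy_conservation_and_refinement_invariance(self, rng):
        for _ in range(50):
            t = random_tile(rng)
            wf = build_pseudowaveform(t, bin_width_m=0.5)
            assert wf.total_energy == pytest.approx(t.intensity.sum(), rel=1e-9)
            wf2 = build_pseudowaveform(t, bin_width_m=0.25)
            assert wf2.total_energy == pytest.approx(wf.total_energy, rel=1e-9)

    def test_bins_span_ground_to_top(self):
        wf = build_pseudowaveform(tile([0.3, 7.9], intensity=[1, 1]), 0.5)
        assert wf.bin_edges[0] == pytest.approx(0.0)
        assert wf.bin_edges[-1] >= 7.9


class TestWaveformMetrics:
    def test_home_symmetric_profile_interpolates_midpoint(self):
        t = tile([3.0, 7.0], intensity=[4.0, 4.0])
        wf = build_pseudowaveform(t, bin_width_m=1.0)
        m = waveform_metrics(wf)
        assert m["HOME"] == pytest.approx(5.0, abs=1e-9)

    def test_all_energy_below_canopy_threshold_gives_zero_aucw(self):
        wf = build_pseudowaveform(tile([0.5, 1.0, 1.5]))
        m = waveform_metrics(wf)
        assert m["AUCW"] == 0.0
        assert m["HOME"] > 0.0  # computed from the full profile

    def test_aucw_strictly_decreases_when_canopy_energy_deleted(self, rng):
        t = random_tile(rng, n_min=50)
        t.intensity = t.intensity + 1.0  # ensure positive canopy energy
        wf = build_pseudowaveform(t)
        base = waveform_metrics(wf)["AUCW"]
        thinned = tile(t.height_m, t.intensity
                       * np.where(t.height_m > 2.0, 0.6, 1.0))
        less = waveform_metrics(build_pseudowaveform(thinned))["AUCW"]
        assert 0 < less < base


class TestRasterize:
    def test_matches_per_tile_oracle_and_order_independence(self, rng):
        tiles = []
        for r in range(2):
            for c in range(3):
                t = random_tile(rng)
                t.cell_id = (r, c)
                tiles.append(t)
        stack = rasterize_metrics(tiles, (2, 3))
        stack_rev = rasterize_metrics(list(reversed(tiles)), (2, 3))
        for t in tiles:
            expected = all_metrics(t)
            for name in METRIC_NAMES:
                assert stack[name][t.cell_id] == pytest.approx(expected[name])
                assert stack_rev[name][t.cell_id] == pytest.approx(expected[name])

    def test_unvisited_cells_are_nodata(self, rng):
        t = random_tile(rng)
        t.cell_id = (0, 0)
        stack = rasterize_metrics([t], (2, 2))
        assert np.isnan(stack["H50"][1, 1])

    def test_misaligned_tile_is_an_error(self, rng):
        t = random_tile(rng)
        t.cell_id = (5, 0)
        with pytest.raises(ValueError):
            rasterize_metrics([t], (2, 2))
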