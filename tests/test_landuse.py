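"""Raster harmonization, masking, change metrics and climate trends."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from landclim import landuse as lu
from landclim.rasters import (CategoricalRaster, read_ascii_grid, read_raster,
                              write_ascii_grid, write_raster)


class TestRasterIO:
    @pytest.mark.parametrize("suffix", ["asc", "tif"])
    def test_roundtrip(self, tmp_path, rng, suffix):
        r = CategoricalRaster(rng.integers(1, 7, (8, 12)), resolution=2.5,
                              origin=(3.0, -1.0))
        path = tmp_path / f"r.{suffix}"
        write_raster(r, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, r.values)
        assert back.resolution == pytest.approx(2.5)
        assert back.origin == pytest.approx((3.0, -1.0))
        assert back.nodata == r.nodata

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            CategoricalRaster(np.zeros((2, 2)))          # floats
        with pytest.raises(ValueError):
            CategoricalRaster(np.zeros((0, 3), dtype=int))


class TestHarmonize:
    def test_identity_map(self, toy_raster_pair):
        hist, _ = toy_raster_pair
        out = lu.harmonize(hist, {c: c for c in range(1, 7)})
        np.testing.assert_array_equal(out.values, hist.values)

    def test_pooling_adds_counts(self):
        # two native heath codes both map to the grassland category
        r = CategoricalRaster(np.array([[10, 11], [10, 3]]))
        out = lu.harmonize(r, {10: 2, 11: 2, 3: 3})
        assert (out.values == 2).sum() == 3
        assert (out.values == 3).sum() == 1

    def test_unmapped_code_is_named(self):
        r = CategoricalRaster(np.array([[1, 99]]))
        with pytest.raises(ValueError, match="99"):
            lu.harmonize(r, {1: 1})

    def test_nodata_preserved(self):
        r = CategoricalRaster(np.array([[1, 255]]), nodata=255)
        out = lu.harmonize(r, {1: 4})
        assert out.values[0, 1] == 255


class TestResample:
    def test_same_resolution_identity(self, toy_raster_pair):
        hist, _ = toy_raster_pair
        out = lu.resample_nearest(hist, hist.resolution)
        np.testing.assert_array_equal(out.values, hist.values)

    def test_upsample_uniform(self):
        r = CategoricalRaster(np.full((2, 2), 5), resolution=2.0)
        out = lu.resample_nearest(r, 1.0)
        assert out.shape == (4, 4)
        assert (out.values == 5).all()

    def test_downsample_checkerboard_nearest_centre(self):
        # 4x4 checkerboard at res 1 -> res 2: each target centre falls in the
        # second row/col of its source block, picking that pixel's value
        vals = np.indices((4, 4)).sum(axis=0) % 2 + 1
        r = CategoricalRaster(vals.astype(np.int64), resolution=1.0)
        out = lu.resample_nearest(r, 2.0)
        expected = vals[np.ix_([1, 3], [1, 3])]
        np.testing.assert_array_equal(out.values, expected)

    def test_incompatible_resolution_rejected(self, toy_raster_pair):
        with pytest.raises(ValueError):
            lu.resample_nearest(toy_raster_pair[0], 0.7)


class TestCommonMask:
    def test_empty_mask_only_aligns_nodata(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        h2 = hist.copy()
        h2.values[0, 0] = h2.nodata
        a, b = lu.apply_common_mask(h2, mod, None)
        assert a.values[0, 0] == a.nodata and b.values[0, 0] == b.nodata
        assert (a.valid == b.valid).all()
        np.testing.assert_array_equal(a.values[a.valid], h2.values[a.valid])

    def test_line_buffer_masks_three_pixel_band(self):
        vals = np.ones((5, 5), dtype=np.int64)
        r1 = CategoricalRaster(vals.copy(), resolution=1.0)
        r2 = CategoricalRaster(vals.copy(), resolution=1.0)
        # horizontal line through the centre row of pixel centres (y=2.5)
        line = LineString([(-1, 2.5), (6, 2.5)])
        a, _ = lu.apply_common_mask(r1, r2, line, buffer_width=1.0)
        masked_rows = np.nonzero((~a.valid).any(axis=1))[0]
        np.testing.assert_array_equal(masked_rows, [1, 2, 3])
        assert (~a.valid)[1:4].all()
        assert a.valid[[0, 4]].all()

    def test_misaligned_rejected(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        shifted = CategoricalRaster(mod.values, resolution=1.0, origin=(1, 0))
        with pytest.raises(ValueError):
            lu.apply_common_mask(hist, shifted, None)


class TestFractionsAndChange:
    def test_uniform_raster(self):
        r = CategoricalRaster(np.full((4, 4), 3), resolution=1.0)
        frac = lu.category_fractions(r, 4.0, categories=[1, 2, 3])
        assert frac.loc["0_0", 3] == 1.0
        assert frac.loc["0_0"].sum() == pytest.approx(1.0)

    def test_hand_counts(self, toy_raster_pair):
        hist, _ = toy_raster_pair
        frac = lu.category_fractions(hist, 4.0)
        assert frac.loc["0_0", 2] == pytest.approx(0.5)
        assert frac.loc["0_0", 3] == pytest.approx(0.25)
        assert frac.loc["0_0", 4] == pytest.approx(0.25)

    def test_fraction_over_valid_pixels_only(self):
        vals = np.full((2, 2), 4, dtype=np.int64)
        vals[0] = 255
        r = CategoricalRaster(vals, nodata=255)
        frac = lu.category_fractions(r, 2.0, categories=[4],
                                     min_valid_fraction=0.5)
        assert frac.loc["0_0", 4] == 1.0

    def test_fully_masked_square_absent(self):
        r = CategoricalRaster(np.full((2, 2), 255), nodata=255)
        assert lu.category_fractions(r, 2.0, categories=[1]).empty

    def test_rows_sum_to_one_and_changes_to_zero(self, small_world):
        fh = lu.category_fractions(small_world.raster_hist, 10.0)
        fm = lu.category_fractions(small_world.raster_mod, 10.0)
        assert np.allclose(fh.sum(axis=1), 1.0, atol=1e-9)
        change = lu.fractional_change(fh, fm)
        assert np.allclose(change.sum(axis=1), 0.0, atol=1e-9)
        assert change.to_numpy().min() >= -1 and change.to_numpy().max() <= 1

    def test_identical_epochs_zero_change(self, small_world):
        fh = lu.category_fractions(small_world.raster_hist, 10.0)
        assert (lu.fractional_change(fh, fh) == 0).all().all()

    def test_toy_full_swap(self):
        a = pd.DataFrame({1: [1.0], 2: [0.0]}, index=["0_0"])
        b = pd.DataFrame({1: [0.0], 2: [1.0]}, index=["0_0"])
        change = lu.fractional_change(a, b)
        assert change.loc["0_0", 1] == -1.0
        assert change.loc["0_0", 2] == 1.0


class TestLandConversion:
    def test_identical_rasters_zero(self, toy_raster_pair):
        hist, _ = toy_raster_pair
        L = lu.land_conversion(hist, hist, 4.0)
        assert L["0_0"] == 0.0

    def test_every_pixel_changes(self):
        a = CategoricalRaster(np.full((2, 2), 1))
        b = CategoricalRaster(np.full((2, 2), 2))
        assert lu.land_conversion(a, b, 2.0)["0_0"] == 1.0

    def test_quarter_changes(self):
        a = CategoricalRaster(np.array([[1, 1], [1, 1]]))
        b = CategoricalRaster(np.array([[2, 1], [1, 1]]))
        assert lu.land_conversion(a, b, 2.0)["0_0"] == 0.25

    def test_conversion_bounds_category_change(self, small_world):
        """Pixel-level change bounds any single category's net change."""
        hist, mod = small_world.raster_hist, small_world.raster_mod
        L = lu.land_conversion(hist, mod, 10.0)
        change = lu.fractional_change(
            lu.category_fractions(hist, 10.0), lu.category_fractions(mod, 10.0))
        assert (L.reindex(change.index) + 1e-12
                >= change.abs().max(axis=1)).all()

    def test_relabelling_invariance(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        perm = {1: 4, 2: 6, 3: 1, 4: 2, 5: 3, 6: 5}
        h2 = lu.harmonize(hist, perm)
        m2 = lu.harmonize(mod, perm)
        pd.testing.assert_series_equal(lu.land_conversion(hist, mod, 4.0),
                                       lu.land_conversion(h2, m2, 4.0))


class TestTransitionMatrix:
    def test_identity_diagonal(self, toy_raster_pair):
        hist, _ = toy_raster_pair
        fate = lu.transition_matrix(hist, hist, 2)
        assert fate[2] == 1.0 and fate.sum() == pytest.approx(1.0)

    def test_total_conversion(self):
        a = CategoricalRaster(np.full((2, 2), 2))
        b = CategoricalRaster(np.full((2, 2), 3))
        fate = lu.transition_matrix(a, b, 2)
        assert fate[3] == 1.0

    def test_hand_tally(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        fate = lu.transition_matrix(hist, mod, 2)
        # of 8 grassland pixels: 3 -> improved (6), 5 stay
        assert fate[6] == pytest.approx(3 / 8)
        assert fate[2] == pytest.approx(5 / 8)
        assert fate.sum() == pytest.approx(1.0)

    def test_absent_category_empty(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        assert lu.transition_matrix(hist, mod, 5).empty

    def test_rows_are_probability_vectors(self, small_world):
        for cat in small_world.raster_hist.categories():
            fate = lu.transition_matrix(small_world.raster_hist,
                                        small_world.raster_mod, int(cat))
            if not fate.empty:
                assert fate.min() >= 0
                assert fate.sum() == pytest.approx(1.0)


class TestSpecialistChange:
    def test_unchanged_habitat_zero(self):
        tab = pd.DataFrame({"change_2": [0.0, 0.0]}, index=["0_0", "1_0"])
        assert (lu.specialist_change(tab, 2) == 0).all()

    def test_retention_sign_convention(self):
        tab = pd.DataFrame({"change_2": [0.5, -0.2]}, index=["a", "b"])
        out = lu.specialist_change(tab, 2)
        assert out["a"] == 0.5 and out["b"] == -0.2

    def test_unknown_habitat_fails(self):
        with pytest.raises(KeyError):
            lu.specialist_change(pd.DataFrame({"change_2": [0.0]}), 9)


class TestTemperatureTrend:
    def test_exact_linear_series(self):
        years = np.arange(1960, 2000)
        temps = 8.0 + 0.02 * (years - 1960)
        assert lu.temperature_trend(years, temps) == pytest.approx(0.2)

    def test_constant_series_zero(self):
        assert lu.temperature_trend(range(1990, 2000), [9.0] * 10) \
            == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        years = np.arange(1961, 2000, dtype=float)
        temps = 8 + 0.015 * years + rng.normal(0, 0.4, len(years))
        xbar, ybar = years.mean(), temps.mean()
        slope = ((years - xbar) @ (temps - ybar)) / ((years - xbar) ** 2).sum()
        assert lu.temperature_trend(years, temps) \
            == pytest.approx(slope * 10, abs=1e-10)

    def test_too_few_points_flagged(self):
        assert lu.temperature_trend([1990, 1991], [8.0, 8.1]) is None

    def test_window_and_monthly_aggregation(self):
        years = np.repeat(np.arange(1990, 2000), 12)
        temps = 8.0 + 0.05 * (years - 1990)      # monthly duplicates
        out = lu.temperature_trend(years, temps, window=(1992, 1997))
        assert out == pytest.approx(0.5)


class TestAgreementUtilities:
    def test_pixel_agreement(self, toy_raster_pair):
        hist, mod = toy_raster_pair
        assert lu.pixel_agreement(hist, mod) == pytest.approx(12 / 16)

    def test_rmsd(self):
        a = pd.DataFrame({1: [0.6], 2: [0.4]}, index=["0_0"])
        b = pd.DataFrame({1: [0.5], 2: [0.5]}, index=["0_0"])
        assert lu.rmsd_per_square(a, b)["0_0"] == pytest.approx(0.1)
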