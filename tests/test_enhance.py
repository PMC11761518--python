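"""Derived-layer formulas, their invariants, and the assist masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapcover.enhance import (
    BASE_KINDS,
    LayerSpec,
    MaskParams,
    black_mask,
    derive_layer,
    steep_slope_mask,
    water_assist_mask,
)
from mapcover.geo_io import GridSpec, MapSheet


def flat_sheet(r, g, b, h=4, w=4, cs=1.0):
    bands = np.zeros((3, h, w), dtype=np.uint8)
    bands[0], bands[1], bands[2] = r, g, b
    return MapSheet("t", bands, GridSpec(0.0, h * cs, cs, h, w))


def random_sheet(seed=0, n=100):
    rng = np.random.default_rng(seed)
    bands = rng.integers(0, 256, (3, n, n), dtype=np.uint8)
    return MapSheet("r", bands, GridSpec(0.0, float(n), 1.0, n, n))


class TestDeriveLayer:
    def test_redness_with_unit_stabiliser(self):
        vals = derive_layer(flat_sheet(100, 50, 50), "redness").values
        assert vals[0, 0] == pytest.approx(100 / 101, abs=1e-6)

    def test_achromatic_pixel(self):
        grey = flat_sheet(120, 120, 120)
        assert derive_layer(grey, "saturation").values[0, 0] == 0.0
        assert derive_layer(grey, "intensity").values[0, 0] == 120.0
        assert derive_layer(grey, "hue").values[0, 0] == 0.0

    def test_normalised_difference_of_ratios(self):
        # hand-computed: redness = 100/101, blueness = 50/151
        red, blue = 100 / 101, 50 / 151
        expected = (red - blue) / (red + blue)
        spec = LayerSpec("nd", "raw", ("redness", "blueness"))
        vals = derive_layer(flat_sheet(100, 50, 50), spec).values
        assert vals[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_unknown_kind_and_variant_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec("brightness")
        with pytest.raises(ValueError):
            LayerSpec("hue", "stretched")

    def test_nodata_propagates(self):
        sheet = flat_sheet(10, 20, 30)
        sheet.nodata_mask[0, 0] = True
        vals = derive_layer(sheet, "redness").values
        assert np.isnan(vals[0, 0]) and not np.isnan(vals[1, 1])

    def test_spec_parse_roundtrip(self):
        for text in ("hue/raw", "redness/hist_norm", "nd(blueness,redness)/raw"):
            assert LayerSpec.parse(text).id == text

    @pytest.mark.parametrize("variant", ["raw", "hist_norm", "inverted"])
    def test_range_invariants_on_random_pixels(self, variant):
        sheet = random_sheet(7, n=320)  # ~1e5 pixels
        for kind in BASE_KINDS:
            vals = derive_layer(sheet, LayerSpec(kind, variant)).values
            if kind == "hue":
                assert vals.min() >= 0 and vals.max() < 360
            elif kind == "saturation":
                assert vals.min() >= -1e-6 and vals.max() <= 1 + 1e-6
            elif kind == "intensity":
                assert vals.min() >= 0 and vals.max() <= 255
            else:
                assert vals.min() >= 0
        nd = derive_layer(
            sheet, LayerSpec("nd", variant, ("redness", "greenness"))
        ).values
        assert nd.min() >= -1 and nd.max() <= 1

    def test_hist_norm_is_monotone(self):
        # per-band rank equalisation preserves order; on a grey sheet the
        # intensity layer exposes the band transform directly
        rng = np.random.default_rng(3)
        grey = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        sheet = MapSheet("g", np.stack([grey] * 3),
                         GridSpec(0.0, 64.0, 1.0, 64, 64))
        raw = derive_layer(sheet, LayerSpec("intensity", "raw")).values.ravel()
        eq = derive_layer(sheet, LayerSpec("intensity", "hist_norm")).values.ravel()
        order = np.argsort(raw, kind="stable")
        assert (np.diff(eq[order]) >= -1e-9).all()

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hue_matches_colorsys(self, r, g, b):
        import colorsys

        vals = derive_layer(flat_sheet(r, g, b, 1, 1), "hue").values
        expected = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)[0] * 360.0
        assert vals[0, 0] == pytest.approx(expected % 360.0, abs=1e-3)


class TestBlackMask:
    def test_dark_achromatic_is_ink(self):
        assert black_mask(flat_sheet(10, 10, 10))[0, 0]

    def test_saturated_red_is_not_ink(self):
        assert not black_mask(flat_sheet(200, 30, 30))[0, 0]

    def test_scene_ink_recall_and_false_hits(self, small_scene):
        ink = black_mask(small_scene.rgb)
        truth = small_scene.ink_truth
        recall = ink[truth].mean()
        false_rate = ink[~truth].mean()
        assert recall >= 0.99
        assert false_rate <= 0.01

    def test_inversion_maps_to_white_mask(self):
        sheet = random_sheet(11, n=64)
        inverted = MapSheet("inv", 255 - sheet.bands, sheet.grid)
        m = black_mask(inverted, MaskParams(black_intensity_max=80))
        original_intensity = sheet.bands.astype(float).mean(axis=0)
        assert (original_intensity[m] >= 255 - 80 - 1e-9).all()


class TestWaterAssist:
    def _lake_sheet(self, rim_width=5, close_shore=True):
        h = w = 60
        bands = np.full((3, h, w), 230, dtype=np.uint8)
        lake = np.zeros((h, w), dtype=bool)
        lake[15:45, 15:45] = True
        from scipy import ndimage

        shore = ndimage.binary_dilation(lake, np.ones((3, 3))) & ~lake
        rim = lake & ~ndimage.binary_erosion(lake, np.ones((2 * rim_width + 1,) * 2))
        for band, v in zip(bands, (70, 110, 200)):
            band[rim] = v
        if close_shore:
            for band in bands:
                band[shore] = 20
        return MapSheet("w", bands, GridSpec(0.0, h, 1.0, h, w)), lake, shore

    def _mask(self, sheet, **kw):
        ink = black_mask(sheet)
        blue = derive_layer(sheet, "blueness")
        return water_assist_mask(sheet, blue, ink, MaskParams(**kw))

    def test_rim_only_lake_filled_completely(self):
        sheet, lake, shore = self._lake_sheet()
        mask = self._mask(sheet)
        assert mask[lake].all()
        assert not mask[~(lake | shore)].any()

    def test_blue_without_enclosure_stays_seed_only(self):
        sheet, lake, _ = self._lake_sheet(close_shore=False)
        mask = self._mask(sheet)
        rim = np.zeros_like(lake)
        blue = derive_layer(sheet, "blueness").values >= 0.9
        assert np.array_equal(mask, blue)

    def test_closed_curve_without_blue_not_filled(self):
        h = w = 40
        bands = np.full((3, h, w), 230, dtype=np.uint8)
        for band in bands:  # a building block outline, no blue inside
            band[10, 10:30] = 20
            band[29, 10:30] = 20
            band[10:30, 10] = 20
            band[10:30, 29] = 20
        sheet = MapSheet("b", bands, GridSpec(0.0, h, 1.0, h, w))
        assert not self._mask(sheet).any()

    def test_monotone_in_blueness_threshold(self, small_scene):
        sheet = small_scene.rgb
        loose = self._mask(sheet, water_blueness_min=0.7)
        strict = self._mask(sheet, water_blueness_min=1.0)
        assert (strict & ~loose).sum() == 0  # lower threshold => superset


class TestSteepSlope:
    def _hachure_field(self, n=300, spacing=20, length=12):
        ink = np.zeros((n, n), dtype=bool)
        for r in range(10, n - length, spacing):
            for c in range(10, n, spacing):
                ink[r:r + length, c] = True
        return ink

    def test_dense_stroke_field_marked_steep(self):
        ink = self._hachure_field()
        mask = steep_slope_mask(ink)  # 25 strokes per 100 m window >= 8
        assert mask[100:200, 100:200].all()

    def test_blank_ink_gives_nothing(self):
        assert not steep_slope_mask(np.zeros((50, 50), dtype=bool)).any()

    def test_long_contours_are_not_strokes(self):
        ink = np.zeros((300, 300), dtype=bool)
        ink[::20, :] = True  # long horizontal lines, length >> range
        assert not steep_slope_mask(ink).any()

    def test_scene_steep_zone_recovered(self, small_scene, small_ctx):
        steep = small_ctx.steep
        truth = small_scene.steep_truth
        if truth.sum() > 2000:
            assert (steep & truth).sum() / truth.sum() > 0.6
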