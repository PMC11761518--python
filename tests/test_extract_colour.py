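"""Symbol detection, rule selection, segmentation and object processing."""

import numpy as np
import pytest

from mapcover.categories import Category
from mapcover.enhance import DerivedLayer, LayerSpec
from mapcover.extract_colour import (
    ExtractionRule,
    InsufficientSymbolsError,
    PipelineConfig,
    RuleBank,
    SheetContext,
    SymbolTemplate,
    detect_symbols,
    extract_category,
    fill_clutter,
    segment_by_rule,
    select_rule,
    smooth_boundaries,
)
from mapcover.geo_io import ConfigError, GridSpec, MapSheet
from mapcover.symbols import heath_glyph, wetland_glyph
from mapcover.synthmap import INTENDED_LAYERS, PAPER_RGB, WASH_RGB


def grid_of(n, cs=1.0):
    return GridSpec(0.0, n * cs, cs, n, n)


class TestDetectSymbols:
    def _stamp_field(self, glyph, n=500, count=25, rng=None):
        ink = np.zeros((n, n), dtype=bool)
        centres = []
        side = int(np.ceil(np.sqrt(count)))
        step = n // (side + 1)
        placed = 0
        for i in range(side):
            for j in range(side):
                if placed >= count:
                    break
                r, c = (i + 1) * step, (j + 1) * step
                h, w = glyph.shape
                ink[r - h // 2:r - h // 2 + h, c - w // 2:c - w // 2 + w] |= glyph
                centres.append((r, c))
                placed += 1
        return ink, centres

    def test_exact_stamps_all_found(self):
        glyph = wetland_glyph()
        ink, centres = self._stamp_field(glyph)
        dets = detect_symbols(ink, SymbolTemplate(Category.wetland, glyph),
                              grid_of(500))
        assert len(dets) == 25
        found = {(d.row, d.col) for d in dets}
        for r, c in centres:
            assert any(abs(r - fr) <= 1 and abs(c - fc) <= 1 for fr, fc in found)

    def test_seeded_dropout_keeps_most_detections(self):
        glyph = heath_glyph()
        ink, _ = self._stamp_field(glyph)
        rng = np.random.default_rng(42)
        on = np.argwhere(ink)
        drop = on[rng.random(len(on)) < 0.2]
        ink[drop[:, 0], drop[:, 1]] = False
        dets = detect_symbols(ink, SymbolTemplate(Category.heath, glyph),
                              grid_of(500))
        assert len(dets) >= 20

    def test_blank_ink_gives_nothing(self):
        dets = detect_symbols(np.zeros((100, 100), dtype=bool),
                              SymbolTemplate(Category.heath, heath_glyph()),
                              grid_of(100))
        assert dets == []

    def test_oversized_template_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            detect_symbols(np.zeros((5, 5), dtype=bool),
                           SymbolTemplate(Category.heath, heath_glyph()),
                           grid_of(5))

    def test_deterministic_ordering(self):
        glyph = wetland_glyph()
        ink, _ = self._stamp_field(glyph, count=9)
        tpl = SymbolTemplate(Category.wetland, glyph)
        a = detect_symbols(ink, tpl, grid_of(500))
        b = detect_symbols(ink, tpl, grid_of(500))
        assert [(d.row, d.col, d.score) for d in a] == \
               [(d.row, d.col, d.score) for d in b]


class TestSelectRule:
    def test_no_detections_is_an_error(self, small_scene, small_ctx):
        bank = RuleBank(candidates={Category.heath: [LayerSpec("redness")]})
        with pytest.raises(InsufficientSymbolsError):
            select_rule(small_scene.rgb, [], bank, Category.heath,
                        small_ctx.ink)

    def test_flat_sheet_ties_break_by_bank_order(self):
        n = 80
        bands = np.full((3, n, n), 128, dtype=np.uint8)
        sheet = MapSheet("flat", bands, grid_of(n))
        ink = np.zeros((n, n), dtype=bool)
        from mapcover.extract_colour import SymbolDetection

        dets = [SymbolDetection(x=float(10 * k + 5), y=float(n - 5), score=1.0,
                                row=4, col=10 * k + 5) for k in range(6)]
        bank = RuleBank(candidates={
            Category.heath: [LayerSpec("redness"), LayerSpec("greenness")]
        })
        rule, scores = select_rule(sheet, dets, bank, Category.heath, ink, seed=0)
        assert rule.layer.id == "redness/raw"  # first candidate wins the tie

    def test_scene_picks_intended_layer_and_covers_symbols(
        self, small_scene, small_ctx
    ):
        cfg = PipelineConfig(seed=5)
        for cat in (Category.wetland, Category.heath):
            layer = extract_category(small_scene.rgb, cat, cfg, small_ctx)
            chosen = layer.provenance["rule_id"].split(":")[1].split(">=")[0].split("<=")[0]
            assert chosen == INTENDED_LAYERS[cat].id
            # segmented extent covers nearly all symbol sites
            grid = small_scene.grid
            hits = 0
            sites = small_scene.symbol_truth[cat]
            for x, y in sites:
                r = int((grid.origin_y - y) / grid.cell_size)
                c = int((x - grid.origin_x) / grid.cell_size)
                hits += bool(layer.label_raster[r, c])
            assert hits >= 0.95 * len(sites)


def brute_force_segment(values, threshold, direction, min_cells):
    """Independent oracle: explicit threshold + BFS labelling + area filter."""
    h, w = values.shape
    passing = [[(values[r][c] >= threshold) if direction == "ge"
                else (values[r][c] <= threshold)
                for c in range(w)] for r in range(h)]
    seen = [[False] * w for _ in range(h)]
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if passing[r][c] and not seen[r][c]:
                comp = [(r, c)]
                seen[r][c] = True
                queue = [(r, c)]
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and passing[nr][nc] \
                                and not seen[nr][nc]:
                            seen[nr][nc] = True
                            comp.append((nr, nc))
                            queue.append((nr, nc))
                if len(comp) >= min_cells:
                    for rr, cc in comp:
                        out[rr, cc] = True
    return out


class TestSegmentByRule:
    def test_uniform_field_single_region(self):
        layer = DerivedLayer(LayerSpec("redness"),
                             np.full((20, 20), 0.9, dtype=np.float32),
                             grid_of(20))
        rule = ExtractionRule(Category.forest, LayerSpec("redness"), 0.5,
                              min_area_m2=10.0, steep_min_area_m2=1.0)
        assert segment_by_rule(layer, rule).all()

    def test_scattered_cells_removed_by_size_filter(self):
        vals = np.zeros((60, 60), dtype=np.float32)
        vals[::7, ::7] = 1.0
        layer = DerivedLayer(LayerSpec("redness"), vals, grid_of(60))
        rule = ExtractionRule(Category.forest, LayerSpec("redness"), 0.5,
                              min_area_m2=2500.0)
        assert not segment_by_rule(layer, rule).any()

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((20, 20)).astype(np.float32)
        thr = float(rng.uniform(0.3, 0.7))
        direction = "ge" if seed % 2 == 0 else "le"
        min_cells = int(rng.integers(1, 8))
        rule = ExtractionRule(Category.forest, LayerSpec("redness"), thr,
                              direction, min_area_m2=float(min_cells),
                              steep_min_area_m2=0.0)
        got = segment_by_rule(DerivedLayer(LayerSpec("redness"), vals,
                                           grid_of(20)), rule)
        expected = brute_force_segment(vals, thr, direction, min_cells)
        assert np.array_equal(got, expected)


class TestFillClutter:
    RULE = ExtractionRule(Category.forest, LayerSpec("redness"), 0.5,
                          min_hole_m2=1000.0)

    def test_ink_hole_filled(self):
        mask = np.ones((9, 9), dtype=bool)
        mask[4, 3:6] = False
        ink = np.zeros_like(mask)
        ink[4, 3:6] = True
        out = fill_clutter(mask, ink, self.RULE, grid_of(9))
        assert out.all()

    def test_large_clean_hole_retained(self):
        mask = np.ones((150, 150), dtype=bool)
        mask[20:120, 20:120] = False  # 10 000 m2 hole, min_hole 1000 m2
        out = fill_clutter(mask, np.zeros_like(mask), self.RULE, grid_of(150))
        assert np.array_equal(out, mask)

    def test_never_unsets_and_changes_confined(self):
        rng = np.random.default_rng(0)
        mask = rng.random((60, 60)) < 0.6
        ink = rng.random((60, 60)) < 0.1
        out = fill_clutter(mask, ink, self.RULE, grid_of(60))
        assert (out | mask).sum() == out.sum()  # monotone growth
        changed = out & ~mask
        # every changed cell was a hole cell: not connected to the border
        from scipy import ndimage

        lab, _ = ndimage.label(~mask, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
        border = set(np.unique(np.concatenate(
            [lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
        assert not any(lab[r, c] in border for r, c in np.argwhere(changed))

    def test_text_strip_makes_object_simply_connected(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        ink = np.zeros_like(mask)
        ink[28:32, 15:45] = True  # text strip inside the object
        holed = mask & ~ink
        out = fill_clutter(holed, ink, self.RULE, grid_of(60))
        assert out[mask].all()
        assert np.array_equal(out & ~holed & ~ink, np.zeros_like(mask))


class TestSmoothBoundaries:
    def test_rectangle_is_stable(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 4:16] = True
        for its in (1, 2, 5):
            assert np.array_equal(smooth_boundaries(mask, its), mask)

    def test_spike_removed_after_one_iteration(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5:, :] = True
        mask[4, 5] = True  # single-cell spike on a straight edge
        out = smooth_boundaries(mask, 1)
        expected = mask.copy()
        expected[4, 5] = False
        assert np.array_equal(out, expected)

    def test_zero_iterations_is_identity(self, rng):
        mask = rng.random((30, 30)) < 0.5
        assert np.array_equal(smooth_boundaries(mask, 0), mask)


class TestExtractCategory:
    def test_dune_sand_routed_to_stipple_module(self, small_scene):
        with pytest.raises(ConfigError, match="stipple"):
            extract_category(small_scene.rgb, Category.dune_sand)

    def test_output_contains_segmentation(self, small_scene, small_ctx):
        layer = extract_category(small_scene.rgb, Category.forest,
                                 small_ctx.cfg, small_ctx)
        assert layer.label_raster is not None and layer.polygons
        assert layer.provenance["rule_id"].startswith("forest")

    def test_steep_patches_recovered_only_inside_steep_mask(self):
        # forest patches of ~150 m2 (< min_area, > steep_min_area) survive
        # inside hachured ground only
        n = 600
        bands = np.empty((3, n, n), dtype=np.uint8)
        for i, v in enumerate(PAPER_RGB):
            bands[i] = v
        forest = WASH_RGB[Category.forest]
        patches_in, patches_out = [(100, 100), (160, 180)], [(400, 420)]
        for r, c in patches_in + patches_out:
            for i in range(3):
                bands[i, r:r + 12, c:c + 13] = forest[i]
        # hachure strokes over the left half only
        for r in range(8, n - 12, 20):
            for c in range(8, 300, 20):
                bands[:, r:r + 12, c] = 20
        sheet = MapSheet("steep", bands, grid_of(n))
        layer = extract_category(sheet, Category.forest)
        seg = layer.label_raster
        for r, c in patches_in:
            assert seg[r + 6, c + 6]
        for r, c in patches_out:
            assert not seg[r + 6, c + 6]
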