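"""Colour-wash category extraction: forest, wetland, heath, water bodies.

The method is threshold segmentation on whichever derived enhancement raster
best isolates the target wash, followed by object processing: clutter filling
under ink, size filtering, boundary regularisation, and a second pass with a
far smaller minimum object size inside the steep-slope mask (where washes are
broken up by hachures).

Forest and (small) water bodies are consistent enough across sheets for a
single fixed (layer + threshold) rule.  Wetland and heath washes vary sheet
by sheet; for those the rule is chosen per sheet from detected occurrences of
the category's point symbol: the candidate layer with the best
signal-vs-background separability around the symbol sites wins and its
threshold is set at the midpoint of the signal and background means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .categories import Category
from .enhance import (
    DerivedLayer,
    LayerSpec,
    MaskParams,
    black_mask,
    derive_layer,
    steep_slope_mask,
    water_assist_mask,
)
from .geo_io import CategoryLayer, ConfigError, GridSpec, MapSheet, vectorize_mask
from .symbols import default_glyphs

__all__ = [
    "ExtractionRule",
    "RuleBank",
    "SymbolTemplate",
    "SymbolDetection",
    "InsufficientSymbolsError",
    "detect_symbols",
    "select_rule",
    "segment_by_rule",
    "fill_clutter",
    "smooth_boundaries",
    "extract_category",
    "SheetContext",
    "default_rule_bank",
    "default_templates",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class InsufficientSymbolsError(RuntimeError):
    """Too few symbol detections on a sheet to choose a rule automatically."""


@dataclass(frozen=True)
class ExtractionRule:
    """A per-category (derived layer + threshold + object size) recipe."""

    category: Category
    layer: LayerSpec
    threshold: float
    direction: str = "ge"  # "ge" or "le"
    min_area_m2: float = 2500.0
    min_hole_m2: float = 1000.0
    steep_min_area_m2: float = 100.0
    smoothing_iterations: int = 2

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "le"):
            raise ValueError("direction must be 'ge' or 'le'")
        if not self.min_area_m2 > self.steep_min_area_m2 >= 0:
            raise ValueError("require min_area_m2 > steep_min_area_m2 >= 0")

    @property
    def rule_id(self) -> str:
        op = ">=" if self.direction == "ge" else "<="
        return f"{self.category.name}:{self.layer.id}{op}{self.threshold:.4g}"

    def test(self, values: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if self.direction == "ge":
                return values >= self.threshold
            return values <= self.threshold


@dataclass
class RuleBank:
    """Fixed rules plus per-sheet candidate lists.

    ``fixed`` holds the single (layer + threshold) rules for the consistent
    categories; ``candidates`` holds the ordered candidate layers among which
    the symbol-driven selector chooses for the variable ones.  Bank order is
    the documented tie-break.
    """

    fixed: dict[Category, ExtractionRule] = field(default_factory=dict)
    candidates: dict[Category, list[LayerSpec]] = field(default_factory=dict)
    min_detections: int = 5
    symbol_radius_m: float = 20.0

    def __post_init__(self) -> None:
        for cat, cands in self.candidates.items():
            if not cands:
                raise ConfigError(f"empty candidate list for {cat}")

    def candidates_for(self, category: Category) -> list[LayerSpec]:
        if category not in self.candidates:
            raise ConfigError(f"no candidate layers configured for {category}")
        return self.candidates[category]


@dataclass(frozen=True)
class SymbolTemplate:
    """A small boolean glyph raster matched against the ink mask."""

    category: Category
    template: np.ndarray
    tau: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", np.asarray(self.template, dtype=bool))
        if not 0 < self.tau <= 1:
            raise ValueError("match threshold tau must be in (0, 1]")


@dataclass(frozen=True)
class SymbolDetection:
    x: float
    y: float
    score: float
    row: int
    col: int


def detect_symbols(
    ink: np.ndarray,
    template: SymbolTemplate,
    grid: GridSpec,
) -> list[SymbolDetection]:
    """Normalised cross-correlation template matching on the ink mask.

    Local maxima with score ≥ τ survive non-maximum suppression within one
    template diameter; results are ordered by (score desc, y, x) so detection
    lists are deterministic.
    """
    tpl = template.template
    if tpl.shape[0] > ink.shape[0] or tpl.shape[1] > ink.shape[1]:
        raise ValueError("template larger than the sheet")
    if not ink.any():
        return []
    # a light blur (sub-pixel sigma) on both sides makes the correlation
    # tolerant to pixel-level ink degradation without blending glyph structure
    sigma = 0.7
    response = match_template(
        ndimage.gaussian_filter(ink.astype(np.float32), sigma),
        ndimage.gaussian_filter(tpl.astype(np.float32), sigma),
        pad_input=True,
    )
    diameter = max(tpl.shape)
    peaks = peak_local_max(
        response,
        min_distance=diameter,
        threshold_abs=template.tau,
        exclude_border=False,
    )
    dets = []
    for r, c in peaks:
        score = float(response[r, c])
        x = grid.origin_x + (c + 0.5) * grid.cell_size
        y = grid.origin_y - (r + 0.5) * grid.cell_size
        dets.append(SymbolDetection(x=x, y=y, score=score, row=int(r), col=int(c)))
    dets.sort(key=lambda d: (-d.score, d.y, d.x))
    return dets


def select_rule(
    sheet: MapSheet,
    detections: list[SymbolDetection],
    bank: RuleBank,
    category: Category,
    ink: np.ndarray,
    seed: int = 0,
    layer_cache: dict | None = None,
) -> ExtractionRule:
    """Choose the best (layer + threshold) rule from symbol detections.

    For every candidate layer the value distribution over non-ink cells
    within ``bank.symbol_radius_m`` of each detection is summarised per
    detection; the signal level is the *median* of the per-detection means
    (so a minority of false detections — a template firing on another
    category's signature — cannot drag the statistic), with the median
    per-detection SD as the signal spread.  The background is an equal count
    of seeded-random non-ink cells.  Separability is
    |signal − background| / pooled SD; the winner takes the midpoint of the
    two levels as threshold, directed toward the signal side.  Ties go to
    the first candidate in bank order.
    """
    if len(detections) < bank.min_detections:
        raise InsufficientSymbolsError(
            f"{category.name}: {len(detections)} symbol detections "
            f"(need >= {bank.min_detections})"
        )
    grid = sheet.grid
    radius_px = int(np.ceil(bank.symbol_radius_m / grid.cell_size))
    yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    disc = (yy * yy + xx * xx) * grid.cell_size**2 <= bank.symbol_radius_m**2
    valid = ~ink & ~sheet.nodata_mask
    h, w = sheet.shape
    windows = []  # per-detection boolean cell masks (as index arrays)
    n_signal = 0
    for det in detections:
        r0, r1 = max(det.row - radius_px, 0), min(det.row + radius_px + 1, h)
        c0, c1 = max(det.col - radius_px, 0), min(det.col + radius_px + 1, w)
        local = disc[r0 - det.row + radius_px:r1 - det.row + radius_px,
                     c0 - det.col + radius_px:c1 - det.col + radius_px]
        sel = local & valid[r0:r1, c0:c1]
        if sel.any():
            rr, cc = np.nonzero(sel)
            windows.append((rr + r0, cc + c0))
            n_signal += len(rr)
    if not windows:
        raise InsufficientSymbolsError(f"{category.name}: no valid signal cells")
    rng = np.random.default_rng(seed)
    flat_valid = np.flatnonzero(valid)
    bg_idx = rng.choice(flat_valid, size=min(n_signal, flat_valid.size),
                        replace=False)

    cache = layer_cache if layer_cache is not None else {}
    best: tuple[float, LayerSpec, float, float] | None = None
    scores: dict[str, float] = {}
    for cand in bank.candidates_for(category):
        if cand.id not in cache:
            cache[cand.id] = derive_layer(sheet, cand)
        vals = cache[cand.id].values
        det_means = [float(np.nanmean(vals[rr, cc])) for rr, cc in windows]
        det_sds = [float(np.nanstd(vals[rr, cc])) for rr, cc in windows]
        mu_s = float(np.median(det_means))
        sd_s = float(np.median(det_sds))
        bg = vals.ravel()[bg_idx]
        mu_b, sd_b = float(np.nanmean(bg)), float(np.nanstd(bg))
        pooled = np.sqrt((sd_s**2 + sd_b**2) / 2.0)
        sep = abs(mu_s - mu_b) / max(pooled, 1e-12)
        scores[cand.id] = sep
        if best is None or sep > best[0]:  # strict > keeps bank-order tie-break
            best = (sep, cand, mu_s, mu_b)
    _, layer_spec, mu_s, mu_b = best
    rule = ExtractionRule(
        category=category,
        layer=layer_spec,
        threshold=(mu_s + mu_b) / 2.0,
        direction="ge" if mu_s >= mu_b else "le",
    )
    return rule, scores


def segment_by_rule(
    layer: DerivedLayer,
    rule: ExtractionRule,
    nodata: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold the layer and keep 4-connected regions ≥ min_area_m2."""
    mask = rule.test(layer.values)
    mask &= ~np.isnan(layer.values)
    if nodata is not None:
        mask &= ~nodata
    return _area_filter(mask, rule.min_area_m2, layer.grid.cell_area)


def _segment_bridged(
    raw: np.ndarray,
    ink: np.ndarray,
    min_area_m2: float,
    cell_area: float,
    bridge_px: int = 3,
) -> np.ndarray:
    """Size-filtered segmentation with thin linework bridged.

    Washes are interrupted by contours, boundaries and text, which would chop
    objects into sub-threshold fragments.  Ink cells lying in a closing of
    the threshold mask (i.e. between wash cells no further than ~2·bridge_px
    apart) are treated as part of the object: they join fragments for the
    minimum-size test and are returned as object cells, which matches the
    drawn extent of the category under its linework.  Wide ink (text blocks)
    and ink bordering wash on one side only are not bridged.
    """
    if not raw.any():
        return raw
    r = bridge_px
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy * yy + xx * xx) <= r * r
    bridged = raw | (ndimage.binary_closing(raw, structure=disk) & ink)
    return _area_filter(bridged, min_area_m2, cell_area)


def _area_filter(mask: np.ndarray, min_area_m2: float, cell_area: float) -> np.ndarray:
    if min_area_m2 <= cell_area or not mask.any():
        return mask
    lab, n = ndimage.label(mask, structure=_CROSS)
    areas = np.bincount(lab.ravel()) * cell_area
    keep = areas >= min_area_m2
    keep[0] = False
    return keep[lab]


def fill_clutter(
    mask: np.ndarray,
    ink: np.ndarray,
    rule: ExtractionRule,
    grid: GridSpec,
) -> np.ndarray:
    """Fill enclosed holes that are small or mostly ink (text / linework).

    A hole (false region fully enclosed by the mask, i.e. not touching the
    raster border) is filled iff its area ≤ min_hole_m2 OR ≥ 50% of its cells
    are ink.  No cell outside holes changes, so filling is monotone.
    """
    inv = ~mask
    if not inv.any():
        return mask
    lab, n = ndimage.label(inv, structure=_CROSS)
    border = np.unique(
        np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    )
    counts = np.bincount(lab.ravel(), minlength=n + 1).astype(np.float64)
    ink_counts = np.bincount(lab[ink], minlength=n + 1).astype(np.float64)
    area = counts * grid.cell_area
    fill = (area <= rule.min_hole_m2) | (ink_counts / np.maximum(counts, 1) >= 0.5)
    fill[0] = False
    fill[border[border > 0]] = False
    if not fill.any():
        return mask
    return mask | fill[lab]


def smooth_boundaries(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Boundary regularisation by 4-neighbour majority voting.

    Each iteration revisits only boundary cells (mixed 4-neighbourhood) and
    flips a cell to the majority of its 4 neighbours; ties keep the current
    value, so flat edges and right-angle corners are stable while single-cell
    spikes and notches are removed.  ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mask.copy()
    kernel = _CROSS.astype(np.uint8).copy()
    kernel[1, 1] = 0
    for _ in range(iterations):
        n4 = ndimage.convolve(out.astype(np.uint8), kernel, mode="constant")
        grow = ~out & (n4 >= 3)
        shrink = out & (n4 <= 1)
        if not grow.any() and not shrink.any():
            break
        out = out | grow
        out &= ~shrink
    return out


# ---------------------------------------------------------------------------
# Defaults and orchestration
# ---------------------------------------------------------------------------

def default_rule_bank() -> RuleBank:
    """Shipped defaults for the synthetic map conventions.

    The fixed forest and water thresholds make no claim of matching any
    original workflow's values — they are configuration, tuned to the wash
    colours the bundled scene generator emulates, and are meant to be
    overridden per archive.
    """
    return RuleBank(
        fixed={
            Category.forest: ExtractionRule(
                Category.forest, LayerSpec("greenness"), 0.62, "ge"
            ),
            Category.water_body: ExtractionRule(
                Category.water_body, LayerSpec("blueness"), 0.85, "ge"
            ),
        },
        candidates={
            Category.wetland: [
                LayerSpec("nd", "raw", ("blueness", "redness")),
                LayerSpec("blueness"),
                LayerSpec("greenness"),
            ],
            # hue is deliberately absent: a circular quantity has no
            # well-defined midpoint threshold, so it is unsuitable for the
            # automated selector's linear rule form
            Category.heath: [
                LayerSpec("redness"),
                LayerSpec("saturation"),
                LayerSpec("greenness"),
            ],
        },
    )


def default_templates(tau: float = 0.8) -> dict[Category, SymbolTemplate]:
    return {
        cat: SymbolTemplate(cat, glyph, tau)
        for cat, glyph in default_glyphs().items()
    }


@dataclass
class PipelineConfig:
    """Everything the per-sheet extraction pipeline needs."""

    bank: RuleBank = field(default_factory=default_rule_bank)
    templates: dict[Category, SymbolTemplate] = field(default_factory=default_templates)
    mask_params: MaskParams = field(default_factory=MaskParams)
    seed: int = 0
    fallback_rules: dict[Category, ExtractionRule] = field(default_factory=dict)


class SheetContext:
    """Caches the per-sheet products shared across category extractions."""

    def __init__(self, sheet: MapSheet, cfg: PipelineConfig):
        self.sheet = sheet
        self.cfg = cfg
        self._layers: dict[str, DerivedLayer] = {}
        self._ink: np.ndarray | None = None
        self._steep: np.ndarray | None = None
        self._water_assist: np.ndarray | None = None

    @property
    def ink(self) -> np.ndarray:
        if self._ink is None:
            self._ink = black_mask(self.sheet, self.cfg.mask_params)
        return self._ink

    @property
    def steep(self) -> np.ndarray:
        if self._steep is None:
            self._steep = steep_slope_mask(
                self.ink, self.cfg.mask_params, self.sheet.grid.cell_size
            )
        return self._steep

    @property
    def water_assist(self) -> np.ndarray:
        if self._water_assist is None:
            self._water_assist = water_assist_mask(
                self.sheet, self.layer(LayerSpec("blueness")), self.ink,
                self.cfg.mask_params,
            )
        return self._water_assist

    def layer(self, spec: LayerSpec) -> DerivedLayer:
        if spec.id not in self._layers:
            self._layers[spec.id] = derive_layer(self.sheet, spec)
        return self._layers[spec.id]


def extract_category(
    sheet: MapSheet,
    category: Category,
    cfg: PipelineConfig | None = None,
    ctx: SheetContext | None = None,
) -> CategoryLayer:
    """Run the full colour pipeline for one category on one sheet.

    Steps: rule resolution (fixed, or symbol-driven for wetland/heath) →
    threshold segmentation with size filter → steep-slope second pass with
    the small threshold → (water only) union with the water assist regions →
    clutter filling → boundary smoothing → polygonisation.  Provenance
    records the applied rule and, where applicable, candidate separabilities
    and detection counts.
    """
    if category == Category.dune_sand:
        raise ConfigError(
            "dune_sand is stipple-mapped; use mapcover.extract_stipple.extract_dune_sand"
        )
    if category not in (Category.forest, Category.wetland, Category.heath,
                        Category.water_body):
        raise ConfigError(f"{category} is not an extraction target")
    cfg = cfg or PipelineConfig()
    ctx = ctx or SheetContext(sheet, cfg)
    grid = sheet.grid
    provenance: dict = {"sheet_id": sheet.sheet_id, "category": category.name}

    if category in cfg.bank.fixed:
        rule = cfg.bank.fixed[category]
    else:
        template = cfg.templates[category]
        detections = detect_symbols(ctx.ink, template, grid)
        provenance["n_detections"] = len(detections)
        try:
            rule, scores = select_rule(
                sheet, detections, cfg.bank, category, ctx.ink,
                seed=cfg.seed, layer_cache=ctx._layers,
            )
            provenance["separability"] = scores
        except InsufficientSymbolsError:
            if category not in cfg.fallback_rules:
                raise
            rule = cfg.fallback_rules[category]
            provenance["fallback"] = True
    provenance["rule_id"] = rule.rule_id
    provenance["threshold"] = rule.threshold

    layer = ctx.layer(rule.layer)
    raw = rule.test(layer.values) & ~np.isnan(layer.values) & ~sheet.nodata_mask
    seg = _segment_bridged(raw, ctx.ink, rule.min_area_m2, grid.cell_area)

    steep = ctx.steep
    if steep.any():
        steep_seg = _area_filter(raw & steep, rule.steep_min_area_m2, grid.cell_area)
        seg = seg | steep_seg

    if category == Category.water_body:
        seg = seg | _area_filter(ctx.water_assist, rule.min_area_m2, grid.cell_area)

    seg = fill_clutter(seg, ctx.ink, rule, grid)
    seg = smooth_boundaries(seg, rule.smoothing_iterations)
    polygons = vectorize_mask(seg, grid, 0.0)
    return CategoryLayer(
        category=category,
        polygons=polygons,
        grid=grid,
        label_raster=seg,
        provenance=provenance,
        sheet_id=sheet.sheet_id,
    )
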