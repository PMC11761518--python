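"""Reassembly of tile and sheet mappings into seamless category layers.

Two reconciliation problems arise when category mapping is run per quarter
tile and per sheet: (i) objects clipped by tile edges can fall below the
minimum object size in each tile although their merged geometry qualifies,
and (ii) mappings can disjoint across sheet borders where the source
material changes.  Overlap-zone objects are therefore re-tested on merged
geometry, and near-border gaps below a tolerance are bridged by convex
filling restricted to an analysis strip along the border.  Bridging never
relabels — geometry only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon, box

from .extract_colour import ExtractionRule
from .geo_io import CategoryLayer, ConfigError, GridSpec

__all__ = ["MosaicParams", "merge_quarters", "resolve_sheet_borders"]


@dataclass(frozen=True)
class MosaicParams:
    border_gap_m: float = 20.0    # max gap bridged across a sheet border
    border_strip_m: float = 50.0  # analysis strip half-width along borders

    def __post_init__(self) -> None:
        if self.border_gap_m <= 0 or self.border_strip_m <= 0:
            raise ValueError("mosaic tolerances must be positive")


def _parts(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    return [g for g in geom.geoms if isinstance(g, Polygon)]


def _overlap_zones(grids: list[GridSpec | None]) -> list[Polygon]:
    boxes = [box(g.extent[0], g.extent[1], g.extent[2], g.extent[3])
             for g in grids if g is not None]
    zones = []
    for a, b in combinations(boxes, 2):
        inter = a.intersection(b)
        if not inter.is_empty and inter.area > 0:
            zones.append(inter)
    return zones


def merge_quarters(
    tiles: list[CategoryLayer],
    rule: ExtractionRule,
) -> CategoryLayer:
    """Merge quarter-tile mappings of one sheet into a single layer.

    The tile polygons are dissolved; merged objects that intersect an
    overlap zone are re-tested against ``rule.min_area_m2`` on their joint
    geometry (parts sub-threshold per tile but jointly large enough
    survive); objects outside overlap zones are kept as delivered.
    """
    if not tiles:
        return CategoryLayer(rule.category, [])
    categories = {t.category for t in tiles}
    if len(categories) != 1:
        raise ConfigError(f"cannot merge mixed categories: {categories}")
    category = tiles[0].category
    zones = _overlap_zones([t.grid for t in tiles])
    zone_union = shapely.unary_union(zones) if zones else None
    merged = shapely.unary_union(
        [p for t in tiles for p in t.polygons]
    )
    out = []
    for part in _parts(merged):
        in_zone = zone_union is not None and part.intersects(zone_union)
        if in_zone and part.area < rule.min_area_m2:
            continue
        out.append(part)
    sheet_ids = {t.sheet_id.rsplit("_q", 1)[0] for t in tiles if t.sheet_id}
    return CategoryLayer(
        category=category,
        polygons=out,
        provenance={
            "operation": "merge_quarters",
            "rule_id": rule.rule_id,
            "n_tiles": len(tiles),
        },
        sheet_id=sheet_ids.pop() if len(sheet_ids) == 1 else "",
    )


def _shared_borders(grids: list[GridSpec | None]) -> list[LineString]:
    """Straight border segments where two sheet extents abut."""
    borders = []
    rects = [g.extent for g in grids if g is not None]
    for (ax0, ay0, ax1, ay1), (bx0, by0, bx1, by1) in combinations(rects, 2):
        # vertical shared edge
        for xa, xb in ((ax1, bx0), (bx1, ax0)):
            if abs(xa - xb) < 1e-6:
                y0, y1 = max(ay0, by0), min(ay1, by1)
                if y1 > y0:
                    borders.append(LineString([(xa, y0), (xa, y1)]))
        # horizontal shared edge
        for ya, yb in ((ay1, by0), (by1, ay0)):
            if abs(ya - yb) < 1e-6:
                x0, x1 = max(ax0, bx0), min(ax1, bx1)
                if x1 > x0:
                    borders.append(LineString([(x0, ya), (x1, ya)]))
    return borders


def resolve_sheet_borders(
    layers: list[CategoryLayer],
    params: MosaicParams = MosaicParams(),
) -> CategoryLayer:
    """Bridge category disjoints across abutting sheet borders.

    Within ``border_strip_m`` of a shared border, polygons from the two
    adjacent sheets whose minimum separation is ≤ ``border_gap_m`` are
    joined by the convex filling of their in-strip parts, clipped to the
    strip (so nothing outside the strip changes).  One-sided polygons pass
    through untouched; the output is dissolved per category.
    """
    if not layers:
        raise ConfigError("no layers to resolve")
    categories = {l.category for l in layers}
    if len(categories) != 1:
        raise ConfigError(f"cannot resolve mixed categories: {categories}")
    category = layers[0].category
    borders = _shared_borders([l.grid for l in layers])
    bridges = []
    bridge_log = []
    for border in borders:
        strip = border.buffer(params.border_strip_m, cap_style="flat")
        for la, lb in combinations(layers, 2):
            if la.grid is None or lb.grid is None:
                continue
            for pa in la.polygons:
                pa_strip = pa.intersection(strip)
                if pa_strip.is_empty:
                    continue
                for pb in lb.polygons:
                    pb_strip = pb.intersection(strip)
                    if pb_strip.is_empty:
                        continue
                    gap = pa_strip.distance(pb_strip)
                    if 0 < gap <= params.border_gap_m:
                        hull = shapely.unary_union([pa_strip, pb_strip]).convex_hull
                        bridges.append(hull.intersection(strip))
                        bridge_log.append(
                            {"gap_m": round(float(gap), 3),
                             "sheets": [la.sheet_id, lb.sheet_id]}
                        )
    dissolved = shapely.unary_union(
        [p for l in layers for p in l.polygons] + bridges
    )
    return CategoryLayer(
        category=category,
        polygons=_parts(dissolved),
        provenance={
            "operation": "resolve_sheet_borders",
            "bridges": bridge_log,
            "border_gap_m": params.border_gap_m,
        },
    )
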