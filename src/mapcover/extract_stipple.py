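"""Dune-sand extraction from black stippling.

Dune sand carries no colour wash — only a regular pattern of small black
dots.  Extraction isolates dot-sized, compact ink objects, then aggregates
them with a density criterion borrowed from density-based clustering: a dot
is *core* when enough other dots fall within the neighbour radius, and the
mapped extent is the dissolved union of buffer discs around core dots and
the dots they reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .categories import Category
from .extract_colour import PipelineConfig, SheetContext, smooth_boundaries
from .geo_io import CategoryLayer, GridSpec, MapSheet, rasterize_layer

__all__ = ["StippleParams", "detect_dots", "aggregate_dots", "extract_dune_sand"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class StippleParams:
    """Dot isolation and aggregation criteria (px / metre units)."""

    dot_area_range_px: tuple[int, int] = (2, 30)
    dot_min_compactness: float = 0.5     # 4*pi*A / P^2
    neighbor_radius_m: float = 25.0
    min_neighbors: int = 3
    dissolve_buffer_m: float = 15.0
    min_region_area_m2: float = 2500.0
    min_hole_m2: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.dot_area_range_px
        if not 0 < lo <= hi:
            raise ValueError("dot_area_range_px must be ordered and positive")
        if self.neighbor_radius_m <= 0 or self.dissolve_buffer_m <= 0:
            raise ValueError("radii must be positive")


def detect_dots(
    ink: np.ndarray,
    params: StippleParams = StippleParams(),
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Centroids (map metres) of dot-sized, compact ink components.

    4-connected ink components with pixel area inside ``dot_area_range_px``
    and compactness 4πA/P² ≥ ``dot_min_compactness`` qualify.  The perimeter
    P counts exposed cell edges.  Centroids are returned as an (n, 2) array
    of (x, y), sorted by (y desc, x) i.e. raster order.
    """
    if grid is None:
        grid = GridSpec(0.0, float(ink.shape[0]), 1.0, *ink.shape)
    if not ink.any():
        return np.empty((0, 2))
    lab, n = ndimage.label(ink, structure=_CROSS)
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    lo, hi = params.dot_area_range_px
    cand = (areas >= lo) & (areas <= hi)
    cand[0] = False
    if not cand.any():
        return np.empty((0, 2))
    # perimeter = exposed 4-edges of each candidate component
    perim = np.zeros(n + 1, dtype=np.int64)
    P = np.pad(lab, 1)
    C = P[1:-1, 1:-1]
    for sl in (P[:-2, 1:-1], P[2:, 1:-1], P[1:-1, :-2], P[1:-1, 2:]):
        exposed = (C != sl) & cand[C]
        perim += np.bincount(C[exposed], minlength=n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        compact = 4.0 * np.pi * areas / np.maximum(perim, 1) ** 2
    keep = cand & (compact >= params.dot_min_compactness)
    ids = np.nonzero(keep)[0]
    if ids.size == 0:
        return np.empty((0, 2))
    cent = np.array(ndimage.center_of_mass(C > 0, C, ids), dtype=float)
    cs = grid.cell_size
    xs = grid.origin_x + (cent[:, 1] + 0.5) * cs
    ys = grid.origin_y - (cent[:, 0] + 0.5) * cs
    pts = np.column_stack([xs, ys])
    order = np.lexsort((pts[:, 0], -pts[:, 1]))  # row-major: y desc, x asc
    return pts[order]


def aggregate_dots(
    dots: np.ndarray,
    params: StippleParams = StippleParams(),
) -> list[Polygon]:
    """Aggregate dot centroids into dune-sand polygons.

    Core dots have ≥ ``min_neighbors`` *other* dots within
    ``neighbor_radius_m``; the extent is the union of
    ``dissolve_buffer_m`` discs around core dots and any dot within reach of
    a core dot, with holes ≤ ``min_hole_m2`` filled and regions below
    ``min_region_area_m2`` dropped.
    """
    dots = np.asarray(dots, dtype=float).reshape(-1, 2)
    if len(dots) == 0:
        return []
    tree = cKDTree(dots)
    neighbor_counts = (
        np.array(tree.query_ball_point(dots, params.neighbor_radius_m,
                                       return_length=True)) - 1
    )
    core = neighbor_counts >= params.min_neighbors
    if not core.any():
        return []
    reach = np.zeros(len(dots), dtype=bool)
    core_tree = cKDTree(dots[core])
    dmin, _ = core_tree.query(dots, k=1)
    reach = dmin <= params.neighbor_radius_m
    member = core | reach
    discs = [Point(x, y).buffer(params.dissolve_buffer_m, quad_segs=8)
             for x, y in dots[member]]
    merged = shapely.unary_union(discs)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    out = []
    for poly in polys:
        if poly.area < params.min_region_area_m2:
            continue
        shell = Polygon(poly.exterior.coords)
        holes = [h for h in poly.interiors
                 if Polygon(h.coords).area > params.min_hole_m2]
        out.append(Polygon(shell.exterior.coords, [h.coords for h in holes]))
    return out


def extract_dune_sand(
    sheet: MapSheet,
    cfg: PipelineConfig | None = None,
    params: StippleParams = StippleParams(),
    ctx: SheetContext | None = None,
) -> CategoryLayer:
    """Full stipple pipeline: ink → dots → density aggregation → smoothing."""
    cfg = cfg or PipelineConfig()
    ctx = ctx or SheetContext(sheet, cfg)
    grid = sheet.grid
    dots = detect_dots(ctx.ink, params, grid)
    polys = aggregate_dots(dots, params)
    provenance = {
        "sheet_id": sheet.sheet_id,
        "category": Category.dune_sand.name,
        "rule_id": "stipple",
        "n_dots": int(len(dots)),
        "params": {
            "neighbor_radius_m": params.neighbor_radius_m,
            "min_neighbors": params.min_neighbors,
            "dissolve_buffer_m": params.dissolve_buffer_m,
        },
    }
    if not polys:
        return CategoryLayer(Category.dune_sand, [], grid, None, provenance,
                             sheet.sheet_id)
    mask = rasterize_layer(polys, grid)
    mask = smooth_boundaries(mask, 2)
    from .geo_io import vectorize_mask

    smoothed = vectorize_mask(mask, grid, 0.0)
    return CategoryLayer(
        category=Category.dune_sand,
        polygons=smoothed,
        grid=grid,
        label_raster=mask,
        provenance=provenance,
        sheet_id=sheet.sheet_id,
    )
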