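"""Georeferenced raster / vector I-O and raster-vector conversion.

Rasters are GeoTIFFs addressed on a projected, metre-unit grid: 0-based pixel
indices, row-major, north-up, half-open windows.  The affine georeferencing is
carried by the standard GeoTIFF ``ModelPixelScale`` and ``ModelTiepoint`` tags
and the CRS label by ``GeoAsciiParams``; nodata uses the ``GDAL_NODATA`` tag.
Vector layers are GeoJSON with map-metre coordinates.

Raster→vector conversion traces exact cell edges so that re-rasterising a
vectorised mask on the same grid reproduces it bit for bit; vector→raster uses
the cell-centre rule (a cell is claimed when its centre lies strictly inside a
polygon).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .categories import Category

__all__ = [
    "FormatError",
    "ConfigError",
    "GridSpec",
    "MapSheet",
    "TilingConfig",
    "CategoryLayer",
    "read_sheet",
    "write_sheet",
    "quarter_sheet",
    "rasterize_layer",
    "vectorize_mask",
    "read_raster",
    "write_raster",
    "write_layer_geojson",
    "read_layer_geojson",
]

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: CRS labels known to be geographic (degree units) — rejected on read.
_GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4258", "EPSG:4269", "EPSG:4230", "CRS:84"}


class FormatError(ValueError):
    """A file does not meet the format contract (band count, CRS, tags)."""


class ConfigError(ValueError):
    """A configuration value is inconsistent with the data it is applied to."""


@dataclass(frozen=True)
class GridSpec:
    """North-up raster grid in a projected metre CRS.

    ``origin`` is the map coordinate of the *top-left corner* of cell (0, 0);
    x grows with column index, y shrinks with row index.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    height: int
    width: int
    crs: str = "EPSG:25832"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map metres."""
        return (
            self.origin_x,
            self.origin_y - self.height * self.cell_size,
            self.origin_x + self.width * self.cell_size,
            self.origin_y,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of cell centres as (x[width], y[height])."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.width) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.height) + 0.5) * cs
        return xs, ys

    def same_grid(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
            and self.height == other.height
            and self.width == other.width
        )

    def window(self, row0: int, row1: int, col0: int, col1: int) -> "GridSpec":
        """Sub-grid for the half-open pixel window [row0:row1, col0:col1]."""
        cs = self.cell_size
        return GridSpec(
            origin_x=self.origin_x + col0 * cs,
            origin_y=self.origin_y - row0 * cs,
            cell_size=cs,
            height=row1 - row0,
            width=col1 - col0,
            crs=self.crs,
        )


@dataclass
class MapSheet:
    """One scanned, georeferenced, hand-coloured map sheet (3 × 8-bit bands)."""

    sheet_id: str
    bands: np.ndarray  # (3, H, W) uint8
    grid: GridSpec
    source: str = "library_scan"  # or "seamless"
    nodata_mask: np.ndarray | None = None  # True where invalid

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[0] != 3:
            raise FormatError(
                f"sheet must have exactly 3 bands, got shape {self.bands.shape}"
            )
        if self.bands.dtype != np.uint8:
            raise FormatError(f"bands must be 8-bit, got {self.bands.dtype}")
        if self.bands.shape[1:] != (self.grid.height, self.grid.width):
            raise FormatError("band shape does not match grid")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.bands.shape[1:], dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    @property
    def red(self) -> np.ndarray:
        return self.bands[0]

    @property
    def green(self) -> np.ndarray:
        return self.bands[1]

    @property
    def blue(self) -> np.ndarray:
        return self.bands[2]


@dataclass(frozen=True)
class TilingConfig:
    """Quarter-tiling with symmetric E-W / N-S overlaps (metres)."""

    overlap_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.overlap_m < 0:
            raise ConfigError("overlap_m must be non-negative")


@dataclass
class CategoryLayer:
    """Polygons of one LULC category, with an optional aligned raster twin."""

    category: Category
    polygons: list[Polygon] = field(default_factory=list)
    grid: GridSpec | None = None
    label_raster: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)
    sheet_id: str = ""

    @property
    def area_m2(self) -> float:
        return float(sum(p.area for p in self.polygons))

    def union(self) -> MultiPolygon | Polygon:
        return shapely.unary_union(self.polygons) if self.polygons else Polygon()


def _check_metric_crs(crs: str) -> None:
    label = crs.strip().upper()
    if label in _GEOGRAPHIC_CRS or "LONGLAT" in label or "DEGREE" in label:
        raise FormatError(f"CRS {crs!r} is not a projected metre-unit CRS")


# ---------------------------------------------------------------------------
# GeoTIFF raster I-O (tifffile with hand-written GeoTIFF tags)
# ---------------------------------------------------------------------------

def _geo_extratags(grid: GridSpec, nodata: float | None) -> list:
    cs = float(grid.cell_size)
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GEO_ASCII, "s", 0, grid.crs + "|"),
    ]
    if nodata is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    return tags


def _read_geotags(page) -> tuple[GridSpec | None, float | None, str]:
    tags = page.tags
    scale = tags.get(_TAG_PIXEL_SCALE)
    tie = tags.get(_TAG_TIEPOINT)
    crs_tag = tags.get(_TAG_GEO_ASCII)
    crs = crs_tag.value.rstrip("|").strip() if crs_tag is not None else ""
    nodata_tag = tags.get(_TAG_GDAL_NODATA)
    nodata = float(nodata_tag.value) if nodata_tag is not None else None
    if scale is None or tie is None:
        return None, nodata, crs
    sx, sy = float(scale.value[0]), float(scale.value[1])
    # tiepoint maps raster (i, j, k) -> map (x, y, z); we require the (0, 0) anchor
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    origin_x = x - j * sx
    origin_y = y + i * sy
    shape = page.shape
    h, w = (shape[0], shape[1]) if len(shape) >= 2 else (shape[0], 1)
    grid = GridSpec(origin_x, origin_y, sx, h, w, crs or "EPSG:25832")
    if not np.isclose(sx, sy):
        raise FormatError("anisotropic cells are not supported")
    return grid, nodata, crs


def write_sheet(sheet: MapSheet, path: str | os.PathLike) -> None:
    """Write a 3-band 8-bit sheet as a georeferenced GeoTIFF."""
    rgb = np.moveaxis(sheet.bands, 0, -1)  # (H, W, 3)
    desc = json.dumps({"sheet_id": sheet.sheet_id, "source": sheet.source})
    tifffile.imwrite(
        path, rgb, photometric="rgb", description=desc,
        extratags=_geo_extratags(sheet.grid, None),
    )


def read_sheet(path: str | os.PathLike) -> MapSheet:
    """Read a georeferenced 3-band GeoTIFF into a :class:`MapSheet`.

    Raises :class:`FormatError` for non-3-band files, missing georeferencing
    or a geographic (degree-unit) CRS.  Cell size is taken as-is: a 0.5 m scan
    stays a 0.5 m sheet — no resampling happens on read.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        grid, _, crs = _read_geotags(page)
        desc = page.tags.get("ImageDescription")
    if data.ndim != 3 or data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 3-band raster, got shape {data.shape}"
        )
    if grid is None:
        raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
    _check_metric_crs(grid.crs)
    meta = {}
    if desc is not None:
        try:
            meta = json.loads(desc.value)
        except (TypeError, ValueError):
            meta = {}
    bands = np.moveaxis(data, -1, 0).astype(np.uint8)
    sheet_id = meta.get("sheet_id", os.path.splitext(os.path.basename(path))[0])
    return MapSheet(
        sheet_id=sheet_id, bands=bands,
        grid=replace(grid, height=data.shape[0], width=data.shape[1]),
        source=meta.get("source", "library_scan"),
    )


def write_raster(
    array: np.ndarray,
    grid: GridSpec,
    path: str | os.PathLike,
    nodata: float | None = None,
    description: str | None = None,
) -> None:
    """Write a single-band raster (float32 layers, uint8 masks/categories)."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype not in (np.dtype(np.uint8), np.dtype(np.float32)):
        arr = arr.astype(np.float32)
    tifffile.imwrite(
        path, arr, description=description or "",
        extratags=_geo_extratags(grid, nodata),
    )


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        grid, _, _ = _read_geotags(page)
    if grid is None:
        raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
    return data, replace(grid, height=data.shape[0], width=data.shape[1])


# ---------------------------------------------------------------------------
# Quarter tiling
# ---------------------------------------------------------------------------

def quarter_sheet(sheet: MapSheet, cfg: TilingConfig = TilingConfig()) -> list[MapSheet]:
    """Cut a sheet into 2 × 2 overlapping quarter tiles.

    Each tile covers its half of the sheet plus ``overlap_m`` beyond the centre
    split, so adjacent tiles share a strip of 2·overlap_m.  Band values are
    copied verbatim, never resampled.  Tiles are returned row-major
    (NW, NE, SW, SE) with sheet ids suffixed ``_q0`` … ``_q3``.
    """
    h, w = sheet.shape
    cs = sheet.grid.cell_size
    ov = int(round(cfg.overlap_m / cs))
    if cfg.overlap_m >= min(h, w) * cs / 2:
        raise ConfigError(
            f"overlap {cfg.overlap_m} m too large for a "
            f"{w * cs:g} x {h * cs:g} m sheet"
        )
    hw, hh = w // 2, h // 2
    col_windows = [(0, hw + ov), (max(hw - ov, 0), w)]
    row_windows = [(0, hh + ov), (max(hh - ov, 0), h)]
    tiles = []
    q = 0
    for r0, r1 in row_windows:
        for c0, c1 in col_windows:
            tiles.append(
                MapSheet(
                    sheet_id=f"{sheet.sheet_id}_q{q}",
                    bands=sheet.bands[:, r0:r1, c0:c1].copy(),
                    grid=sheet.grid.window(r0, r1, c0, c1),
                    source=sheet.source,
                    nodata_mask=sheet.nodata_mask[r0:r1, c0:c1].copy(),
                )
            )
            q += 1
    return tiles


# ---------------------------------------------------------------------------
# Vector <-> raster
# ---------------------------------------------------------------------------

def rasterize_layer(
    polygons: CategoryLayer | list[Polygon] | Polygon | MultiPolygon,
    grid: GridSpec,
    crs: str | None = None,
) -> np.ndarray:
    """Burn polygons onto a grid with the cell-centre rule.

    A cell is True iff its centre lies strictly inside a polygon (even-odd
    rule); centres exactly on a boundary are outside.  When a
    :class:`CategoryLayer` with its own grid/CRS is passed, the CRS labels
    must agree.
    """
    if isinstance(polygons, CategoryLayer):
        layer_crs = polygons.grid.crs if polygons.grid is not None else None
        if layer_crs is not None and layer_crs != grid.crs:
            raise FormatError(f"CRS mismatch: layer {layer_crs} vs grid {grid.crs}")
        geoms = polygons.polygons
    elif isinstance(polygons, (Polygon, MultiPolygon)):
        geoms = [polygons]
    else:
        geoms = list(polygons)
    if crs is not None and crs != grid.crs:
        raise FormatError(f"CRS mismatch: {crs} vs grid {grid.crs}")
    out = np.zeros((grid.height, grid.width), dtype=bool)
    geoms = [g for g in geoms if not g.is_empty]
    if not geoms:
        return out
    geom = shapely.unary_union(geoms) if len(geoms) > 1 else geoms[0]
    shapely.prepare(geom)
    xs, ys = grid.cell_centres()
    # restrict the point-in-polygon test to the geometry's bounding window
    xmin, ymin, xmax, ymax = geom.bounds
    jmask = (xs >= xmin - grid.cell_size) & (xs <= xmax + grid.cell_size)
    imask = (ys >= ymin - grid.cell_size) & (ys <= ymax + grid.cell_size)
    jj = np.nonzero(jmask)[0]
    ii = np.nonzero(imask)[0]
    if len(jj) == 0 or len(ii) == 0:
        return out
    gx, gy = np.meshgrid(xs[jj], ys[ii])
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    out[np.ix_(ii, jj)] = inside
    return out


def _stitch_rings(edges: dict[int, list[int]], stride: int) -> list[list[tuple[int, int]]]:
    """Assemble directed cell-edge segments into closed rings.

    Vertices are encoded as ``row * stride + col``.  At ambiguous vertices
    (diagonal pinches) the sharpest right turn is taken, which keeps
    4-connected regions and their holes as separate simple rings.
    """
    rings: list[list[tuple[int, int]]] = []
    # edges: start vertex -> list of end vertices (consumed as we go).
    # Start rings at unambiguous vertices (one outgoing edge) so that pinch
    # vertices are always resolved with a known incoming direction.
    starts = sorted(edges.keys(), key=lambda v: (len(edges[v]) > 1, v))
    for start in starts:
        while edges.get(start):
            ring = [start]
            prev = None
            cur = start
            while True:
                outs = edges.get(cur)
                if not outs:
                    break  # defensive; should not happen on closed boundaries
                if len(outs) == 1 or prev is None:
                    nxt = outs.pop()
                else:
                    # left-turn preference relative to the incoming direction:
                    # hugging the exterior side keeps shell and hole edges
                    # correctly paired at diagonal pinch vertices
                    pr, pc = divmod(prev, stride)
                    cr, cc = divmod(cur, stride)
                    dr, dc = cr - pr, cc - pc
                    pref = [(-dc, dr), (dr, dc), (dc, -dr)]
                    nxt = None
                    for tr, tc in pref:
                        cand = (cr + tr) * stride + (cc + tc)
                        if cand in outs:
                            outs.remove(cand)
                            nxt = cand
                            break
                    if nxt is None:
                        nxt = outs.pop()
                if not outs:
                    edges.pop(cur, None)
                prev, cur = cur, nxt
                if cur == start:
                    break
                ring.append(cur)
            rings.append([divmod(v, stride) for v in ring])
    return rings


def vectorize_mask(
    mask: np.ndarray,
    grid: GridSpec,
    min_area_m2: float = 0.0,
) -> list[Polygon]:
    """Trace 4-connected True regions into exact cell-edge polygons.

    Regions smaller than ``min_area_m2`` are dropped.  Re-rasterising the
    result on ``grid`` reproduces the retained regions exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.height, grid.width):
        raise FormatError("mask shape does not match grid")
    if not mask.any():
        return []
    lab, n = ndimage.label(mask, structure=_CROSS)
    cell_area = grid.cell_area
    areas = np.bincount(lab.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] * cell_area >= min_area_m2
    if not keep.any():
        return []

    P = np.pad(lab, 1)
    C = P[1:-1, 1:-1]
    active = keep[C]
    stride = grid.width + 2  # vertex columns run 0..width
    region_edges: dict[int, dict[int, list[int]]] = {}

    def _add(rr: np.ndarray, cc: np.ndarray, sv_r, sv_c, ev_r, ev_c) -> None:
        regions = C[rr, cc]
        sv = (rr + sv_r) * stride + (cc + sv_c)
        ev = (rr + ev_r) * stride + (cc + ev_c)
        for reg, s, e in zip(regions.tolist(), sv.tolist(), ev.tolist()):
            region_edges.setdefault(reg, {}).setdefault(s, []).append(e)

    north = active & (P[:-2, 1:-1] != C)
    south = active & (P[2:, 1:-1] != C)
    west = active & (P[1:-1, :-2] != C)
    east = active & (P[1:-1, 2:] != C)
    rr, cc = np.nonzero(north)
    _add(rr, cc, 0, 0, 0, 1)          # TL -> TR
    rr, cc = np.nonzero(east)
    _add(rr, cc, 0, 1, 1, 1)          # TR -> BR
    rr, cc = np.nonzero(south)
    _add(rr, cc, 1, 1, 1, 0)          # BR -> BL
    rr, cc = np.nonzero(west)
    _add(rr, cc, 1, 0, 0, 0)          # BL -> TL

    cs = grid.cell_size
    x0, y0 = grid.origin_x, grid.origin_y
    polygons: list[Polygon] = []
    for reg in sorted(region_edges):
        rings = _stitch_rings(region_edges[reg], stride)
        shells: list[tuple[Polygon, list]] = []
        holes: list[list[tuple[float, float]]] = []
        for ring in rings:
            coords = [(x0 + c * cs, y0 - r * cs) for r, c in ring]
            if len(coords) < 3:
                continue
            # boundary is traced with the region interior on the right, which
            # after the row->y flip makes shells negative-signed and holes
            # positive-signed
            if _signed_area(coords) < 0:
                shells.append((Polygon(coords), []))
            else:
                holes.append(coords)
        for hole in holes:
            pt = shapely.Polygon(hole).representative_point()
            for shell_poly, shell_holes in shells:
                if shell_poly.contains(pt):
                    shell_holes.append(hole)
                    break
        for shell_poly, shell_holes in shells:
            poly = (Polygon(shell_poly.exterior.coords, shell_holes)
                    if shell_holes else shell_poly)
            if not poly.is_valid:  # degenerate pinch geometry: repair
                repaired = shapely.make_valid(poly)
                polygons.extend(_polygon_parts(repaired))
            else:
                polygons.append(poly)
    return polygons


def _polygon_parts(geom) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom] if not geom.is_empty else []
    if hasattr(geom, "geoms"):
        return [p for g in geom.geoms for p in _polygon_parts(g)
                if not p.is_empty]
    return []


def _signed_area(coords: list[tuple[float, float]]) -> float:
    xs = np.array([c[0] for c in coords] + [coords[0][0]])
    ys = np.array([c[1] for c in coords] + [coords[0][1]])
    return 0.5 * float(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1]))


# ---------------------------------------------------------------------------
# Vector layer I-O (GeoJSON)
# ---------------------------------------------------------------------------

def write_layer_geojson(layer: CategoryLayer, path: str | os.PathLike) -> None:
    feats = []
    rule_id = str(layer.provenance.get("rule_id", ""))
    for poly in layer.polygons:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "category": layer.category.name,
                    "sheet_id": layer.sheet_id,
                    "rule_id": rule_id,
                    "area_m2": round(poly.area, 6),
                },
            }
        )
    crs = layer.grid.crs if layer.grid is not None else "EPSG:25832"
    doc = {
        "type": "FeatureCollection",
        "mapcover:crs": crs,
        "mapcover:provenance": _jsonable(layer.provenance),
        "features": feats,
    }
    if layer.grid is not None:
        g = layer.grid
        doc["mapcover:grid"] = [g.origin_x, g.origin_y, g.cell_size,
                                g.height, g.width, g.crs]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_layer_geojson(path: str | os.PathLike) -> CategoryLayer:
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    polygons = []
    category = Category.other
    sheet_id = ""
    for feat in feats:
        geom = shape(feat["geometry"])
        if isinstance(geom, MultiPolygon):
            polygons.extend(list(geom.geoms))
        else:
            polygons.append(geom)
        props = feat.get("properties", {})
        if "category" in props:
            category = Category[props["category"]]
        sheet_id = props.get("sheet_id", sheet_id)
    grid = None
    if "mapcover:grid" in doc:
        ox, oy, cs, h, w, crs = doc["mapcover:grid"]
        grid = GridSpec(ox, oy, cs, int(h), int(w), crs)
    return CategoryLayer(
        category=category,
        polygons=polygons,
        grid=grid,
        provenance=doc.get("mapcover:provenance", {}),
        sheet_id=sheet_id,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Category):
        return obj.name
    return obj
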