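"""Derived enhancement layers and assist masks.

Hand-coloured map sheets are separated into content classes by simple colour
algebra rather than learned features: hue/saturation/intensity transforms and
the band ratios redness R/(G+B), greenness G/(R+B) and blueness B/(R+G),
each computable on raw, histogram-normalised or inverted band values, plus
normalised differences of any ordered pair of those layers.  Ratio and
normalised-difference layers are insensitive to the multiplicative brightness
fades common in scanned hand-coloured sheets, which is what makes them useful
segmentation bases.

Three assist masks are derived from the same algebra:

* the *black-parts* mask — all ink (linework, text, symbols, stippling),
* the *water assist* mask — the postulated full extent of large water bodies
  whose blue wash covers only the near-shore zone inside a solid shoreline,
* the *steep-slope* mask — zones of dense short hachure strokes drawn
  between height contours.

Masks are plain boolean numpy rasters aligned to the sheet grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .geo_io import GridSpec, MapSheet

__all__ = [
    "BASE_KINDS",
    "LayerSpec",
    "DerivedLayer",
    "MaskParams",
    "derive_layer",
    "black_mask",
    "water_assist_mask",
    "steep_slope_mask",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

BASE_KINDS = ("hue", "saturation", "intensity", "redness", "greenness", "blueness")
_VARIANTS = ("raw", "hist_norm", "inverted")


@dataclass(frozen=True)
class LayerSpec:
    """Identifies one derived layer: a base kind or an nd(a, b) pair.

    ``variant`` transforms the 8-bit band values *before* the colour algebra:
    ``inverted`` is 255 − value; ``hist_norm`` is per-band average-rank
    equalisation over valid cells, rescaled to [0, 255] so the downstream
    formulas keep their 8-bit-scale interpretation.
    """

    kind: str
    variant: str = "raw"
    nd_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind == "nd":
            if not self.nd_pair or len(self.nd_pair) != 2:
                raise ValueError("nd layer requires an ordered (a, b) kind pair")
            for k in self.nd_pair:
                if k not in BASE_KINDS:
                    raise ValueError(f"unknown nd operand kind: {k!r}")
        elif self.kind not in BASE_KINDS:
            raise ValueError(f"unknown layer kind: {self.kind!r}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant: {self.variant!r}")

    @property
    def id(self) -> str:
        if self.kind == "nd":
            return f"nd({self.nd_pair[0]},{self.nd_pair[1]})/{self.variant}"
        return f"{self.kind}/{self.variant}"

    @classmethod
    def parse(cls, text: str) -> "LayerSpec":
        """Parse ``"kind/variant"`` or ``"nd(a,b)/variant"`` identifiers."""
        text = text.strip()
        variant = "raw"
        if "/" in text:
            text, variant = text.rsplit("/", 1)
        if text.startswith("nd(") and text.endswith(")"):
            a, b = (s.strip() for s in text[3:-1].split(","))
            return cls("nd", variant, (a, b))
        return cls(text, variant)


@dataclass
class DerivedLayer:
    """A real-valued enhancement raster aligned to its source sheet."""

    spec: LayerSpec
    values: np.ndarray  # float32, NaN where nodata
    grid: GridSpec


@dataclass(frozen=True)
class MaskParams:
    """Free parameters of the assist masks (8-bit / metre units)."""

    black_intensity_max: float = 80.0
    black_saturation_max: float = 0.25
    water_blueness_min: float = 0.9
    hachure_len_range: tuple[float, float] = (3.0, 25.0)
    hachure_min_eccentricity: float = 0.9
    hachure_density_min: float = 8.0  # strokes per 100 m x 100 m window
    density_window_m: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.black_intensity_max <= 255:
            raise ValueError("black_intensity_max out of 8-bit range")
        if not 0 <= self.black_saturation_max <= 1:
            raise ValueError("black_saturation_max out of [0, 1]")
        lo, hi = self.hachure_len_range
        if not 0 < lo < hi:
            raise ValueError("hachure_len_range must be ordered and positive")


def _hist_norm_band(band: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Average-rank equalisation of an 8-bit band, rescaled to [0, 255]."""
    vals = band[valid]
    n = vals.size
    if n == 0:
        return band.astype(np.float64)
    counts = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    below = np.concatenate(([0.0], np.cumsum(counts)[:-1]))
    # average rank of each grey value, mapped to [0, 1]
    rank01 = np.where(counts > 0, (below + (counts + 1) / 2.0) / n, 0.0)
    out = rank01[band] * 255.0
    return out


def _prepared_bands(sheet: MapSheet, variant: str) -> np.ndarray:
    bands = sheet.bands.astype(np.float64)
    if variant == "inverted":
        bands = 255.0 - bands
    elif variant == "hist_norm":
        valid = ~sheet.nodata_mask
        bands = np.stack([_hist_norm_band(sheet.bands[i], valid) for i in range(3)])
    return bands


def _base_layer(bands: np.ndarray, kind: str) -> np.ndarray:
    r, g, b = bands
    if kind == "intensity":
        return (r + g + b) / 3.0
    if kind == "saturation":
        intensity = (r + g + b) / 3.0
        return 1.0 - np.minimum(np.minimum(r, g), b) / np.maximum(intensity, 1.0)
    if kind == "hue":
        # standard hexcone hue, degrees in [0, 360); achromatic cells -> 0
        mx = np.maximum(np.maximum(r, g), b)
        mn = np.minimum(np.minimum(r, g), b)
        delta = mx - mn
        hue = np.zeros_like(r)
        with np.errstate(invalid="ignore", divide="ignore"):
            dm = np.where(delta > 0, delta, 1.0)
            hr = np.mod((g - b) / dm, 6.0)
            hg = (b - r) / dm + 2.0
            hb = (r - g) / dm + 4.0
        hue = np.where(mx == r, hr, np.where(mx == g, hg, hb))
        hue = np.where(delta > 0, hue * 60.0, 0.0)
        return np.mod(hue, 360.0)
    # ratio layers; the +1 stabiliser keeps zero denominators finite
    if kind == "redness":
        return r / (g + b + 1.0)
    if kind == "greenness":
        return g / (r + b + 1.0)
    if kind == "blueness":
        return b / (r + g + 1.0)
    raise ValueError(f"unknown layer kind: {kind!r}")


def derive_layer(sheet: MapSheet, spec: LayerSpec | str) -> DerivedLayer:
    """Compute one derived enhancement raster for a sheet.

    nd(a, b) is (a − b)/(a + b) on the two (non-negative) base layers of the
    same variant, defined as 0 where both operands are 0.  Nodata cells
    propagate as NaN.
    """
    if isinstance(spec, str):
        spec = LayerSpec.parse(spec)
    bands = _prepared_bands(sheet, spec.variant)
    if spec.kind == "nd":
        a = _base_layer(bands, spec.nd_pair[0])
        b = _base_layer(bands, spec.nd_pair[1])
        denom = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        values = _base_layer(bands, spec.kind)
    values = values.astype(np.float32)
    if sheet.nodata_mask is not None and sheet.nodata_mask.any():
        values[sheet.nodata_mask] = np.nan
    return DerivedLayer(spec=spec, values=values, grid=sheet.grid)


def black_mask(sheet: MapSheet, params: MaskParams = MaskParams()) -> np.ndarray:
    """All-ink mask: dark *and* unsaturated cells (text, linework, symbols)."""
    bands = sheet.bands.astype(np.float64)
    intensity = _base_layer(bands, "intensity")
    saturation = _base_layer(bands, "saturation")
    mask = (intensity <= params.black_intensity_max) & (
        saturation <= params.black_saturation_max
    )
    mask &= ~sheet.nodata_mask
    return mask


def water_assist_mask(
    sheet: MapSheet,
    blueness: DerivedLayer,
    ink: np.ndarray,
    params: MaskParams = MaskParams(),
) -> np.ndarray:
    """Postulated full extent of water bodies from blue seeds and shorelines.

    Water surfaces are bounded by solid black shorelines but are often washed
    blue only near the shore.  Any region of non-ink cells that is fully
    enclosed by ink (after one 3 × 3 morphological closing to bridge one-cell
    gaps) and contains at least one blue seed cell
    (blueness ≥ ``water_blueness_min``) is filled entirely; blue seeds outside
    any closed curve are kept as-is.
    """
    seeds = np.asarray(blueness.values >= params.water_blueness_min)
    seeds &= ~ink
    seeds &= ~sheet.nodata_mask
    closed_ink = ndimage.binary_closing(ink, structure=np.ones((3, 3), bool))
    open_space = ~closed_ink
    lab, _ = ndimage.label(open_space, structure=_CROSS)
    # exterior = open-space components touching the raster border
    border = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    exterior = np.unique(border[border > 0])
    seed_regions = np.unique(lab[seeds & open_space])
    seed_regions = seed_regions[seed_regions > 0]
    fill = np.setdiff1d(seed_regions, exterior, assume_unique=False)
    mask = np.isin(lab, fill) if fill.size else np.zeros_like(ink)
    return mask | seeds


def steep_slope_mask(
    ink: np.ndarray,
    params: MaskParams = MaskParams(),
    cell_size: float = 1.0,
) -> np.ndarray:
    """Mask of steeply sloping ground from hachure-stroke density.

    Ink components whose skeleton length falls in ``hachure_len_range`` and
    whose eccentricity is at least ``hachure_min_eccentricity`` count as
    strokes; cells where the stroke count within the sliding density window
    reaches ``hachure_density_min`` are steep, dilated by one half window to
    cover inter-stroke gaps.
    """
    out = np.zeros_like(ink, dtype=bool)
    if not ink.any():
        return out
    lab, n = ndimage.label(ink, structure=_CROSS)
    areas = np.bincount(lab.ravel())
    lo, hi = params.hachure_len_range
    lo_px, hi_px = lo / cell_size, hi / cell_size
    # skeleton length <= area, so components larger than ~3 cells per skeleton
    # cell cannot be strokes; pre-filter to keep skeletonisation cheap
    cand = np.zeros(n + 1, dtype=bool)
    cand[1:] = (areas[1:] >= lo_px) & (areas[1:] <= hi_px * 3.0)
    if not cand.any():
        return out
    small = cand[lab]
    skel = skeletonize(small)
    skel_len = np.bincount(lab[skel], minlength=n + 1).astype(np.float64)
    ecc = _component_eccentricity(lab, n)
    stroke = (
        cand
        & (skel_len * cell_size >= lo)
        & (skel_len * cell_size <= hi)
        & (ecc >= params.hachure_min_eccentricity)
    )
    stroke[0] = False
    if not stroke.any():
        return out
    # one indicator cell per stroke at its centroid
    cent = np.array(
        ndimage.center_of_mass(small, lab, np.nonzero(stroke)[0]), dtype=float
    )
    ind = np.zeros(ink.shape, dtype=np.float64)
    rr = np.clip(np.round(cent[:, 0]).astype(int), 0, ink.shape[0] - 1)
    cc = np.clip(np.round(cent[:, 1]).astype(int), 0, ink.shape[1] - 1)
    np.add.at(ind, (rr, cc), 1.0)
    win = max(int(round(params.density_window_m / cell_size)), 1)
    counts = ndimage.uniform_filter(ind, size=win, mode="constant") * win * win
    dense = counts >= params.hachure_density_min - 1e-9
    half = win // 2
    if dense.any() and half > 0:
        dense = ndimage.maximum_filter(dense, size=2 * half + 1, mode="constant")
    return dense


def _component_eccentricity(lab: np.ndarray, n: int) -> np.ndarray:
    """Eccentricity of each labelled component from its second moments."""
    flat = lab.ravel()
    rows, cols = np.indices(lab.shape)
    r = rows.ravel().astype(np.float64)
    c = cols.ravel().astype(np.float64)
    cnt = np.bincount(flat, minlength=n + 1).astype(np.float64)
    cnt_safe = np.maximum(cnt, 1.0)
    mr = np.bincount(flat, weights=r, minlength=n + 1) / cnt_safe
    mc = np.bincount(flat, weights=c, minlength=n + 1) / cnt_safe
    # central second moments with the 1/12 cell term (matches regionprops)
    srr = np.bincount(flat, weights=r * r, minlength=n + 1) / cnt_safe - mr**2 + 1 / 12
    scc = np.bincount(flat, weights=c * c, minlength=n + 1) / cnt_safe - mc**2 + 1 / 12
    src = np.bincount(flat, weights=r * c, minlength=n + 1) / cnt_safe - mr * mc
    tr = srr + scc
    det = srr * scc - src * src
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    l1 = tr / 2.0 + disc
    l2 = tr / 2.0 - disc
    with np.errstate(invalid="ignore", divide="ignore"):
        ecc = np.sqrt(np.maximum(1.0 - l2 / np.maximum(l1, 1e-12), 0.0))
    ecc[cnt == 0] = 0.0
    return ecc
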