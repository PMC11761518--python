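"""Historical-vs-contemporary land-cover change analysis.

Historical category layers, rasterised to the contemporary grid, are compared
cell by cell.  Small delineation discrepancies between two independently
drawn maps would otherwise masquerade as change, so historical cells whose
category re-occurs in the contemporary map within an alignment distance are
re-coded *aligned-stable* and count as stable downstream.  The comparison
yields a from→to transition matrix, per-category loss/stable/gain rasters,
and a flow table suitable for Sankey tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .categories import TARGET_CATEGORIES, Category
from .geo_io import FormatError

__all__ = [
    "ChangeConfig",
    "AlignedRaster",
    "TransitionMatrix",
    "align_categories",
    "transition_matrix",
    "loss_stable_gain",
    "flow_table",
    "CHANGE_CODES",
]

#: loss/stable/gain raster codes
CHANGE_CODES = {"none": 0, "lost": 1, "stable": 2, "gained": 3}


@dataclass(frozen=True)
class ChangeConfig:
    cell_size_m: float = 10.0
    align_max_dist_m: float = 40.0
    sea_mask: np.ndarray | None = None  # True where sea (splits water bodies)

    def __post_init__(self) -> None:
        if self.align_max_dist_m < 0:
            raise ValueError("align_max_dist_m must be >= 0")
        ratio = self.align_max_dist_m / self.cell_size_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("align_max_dist_m must be a multiple of cell_size_m")


@dataclass
class AlignedRaster:
    """Historical codes plus the cells re-coded aligned-stable."""

    codes: np.ndarray            # historical category codes (unchanged)
    aligned_stable: np.ndarray   # True where re-coded as stable


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # index = from (historical), columns = to (contemporary)
    cell_size_m: float

    @property
    def areas_km2(self) -> pd.DataFrame:
        return self.counts * (self.cell_size_m**2) / 1e6

    @property
    def n_cells(self) -> int:
        return int(self.counts.values.sum())


def align_categories(
    hist: np.ndarray,
    contemp: np.ndarray,
    cfg: ChangeConfig = ChangeConfig(),
) -> AlignedRaster:
    """Re-code near-miss historical cells of the five targets as stable.

    A historical cell of target category c that disagrees with the
    contemporary label but lies within ``align_max_dist_m`` (cell-centre
    Euclidean distance) of a contemporary cell of c becomes aligned-stable c.
    Cells that already agree, and non-target categories, are never touched.
    Alignment is one-directional: historical toward contemporary.
    """
    hist = np.asarray(hist)
    contemp = np.asarray(contemp)
    if hist.shape != contemp.shape:
        raise FormatError("historical and contemporary rasters must share a grid")
    aligned = np.zeros(hist.shape, dtype=bool)
    if cfg.align_max_dist_m == 0:
        return AlignedRaster(codes=hist.copy(), aligned_stable=aligned)
    max_px = cfg.align_max_dist_m / cfg.cell_size_m
    for cat in TARGET_CATEGORIES:
        code = cat.value
        mismatch = (hist == code) & (contemp != code)
        if not mismatch.any():
            continue
        has_target = contemp == code
        if not has_target.any():
            continue
        dist = ndimage.distance_transform_edt(~has_target)
        aligned |= mismatch & (dist <= max_px + 1e-9)
    return AlignedRaster(codes=hist.copy(), aligned_stable=aligned)


def _category_names(*rasters: np.ndarray) -> list[str]:
    codes = sorted(set(np.unique(np.concatenate([r.ravel() for r in rasters]))))
    return [Category(int(c)).name for c in codes]


def transition_matrix(
    hist_aligned: AlignedRaster | np.ndarray,
    contemp: np.ndarray,
    cfg: ChangeConfig = ChangeConfig(),
) -> TransitionMatrix:
    """Cell-count cross-tabulation of historical→contemporary categories.

    Aligned-stable cells of category c count on the (c, c) diagonal, so row
    sums always equal the historical category cell counts.
    """
    if isinstance(hist_aligned, np.ndarray):
        hist_aligned = AlignedRaster(hist_aligned, np.zeros(hist_aligned.shape, bool))
    hist = hist_aligned.codes
    if hist.shape != contemp.shape:
        raise FormatError("rasters must share a grid")
    to = np.where(hist_aligned.aligned_stable, hist, contemp)
    names = _category_names(hist, contemp)
    codes = [Category[n].value for n in names]
    index = {c: i for i, c in enumerate(codes)}
    ncat = len(codes)
    flat = np.zeros(ncat * ncat, dtype=np.int64)
    hi = np.vectorize(index.get, otypes=[np.int64])(hist.ravel())
    ti = np.vectorize(index.get, otypes=[np.int64])(to.ravel())
    np.add.at(flat, hi * ncat + ti, 1)
    counts = pd.DataFrame(flat.reshape(ncat, ncat), index=names, columns=names)
    return TransitionMatrix(counts=counts, cell_size_m=cfg.cell_size_m)


def loss_stable_gain(
    hist_aligned: AlignedRaster | np.ndarray,
    contemp: np.ndarray,
    category: Category,
) -> np.ndarray:
    """Per-cell change class for one category (codes in CHANGE_CODES).

    stable: c→c including aligned-stable; lost: c→¬c; gained: ¬c→c.
    The three classes are mutually exclusive by construction.
    """
    if isinstance(hist_aligned, np.ndarray):
        hist_aligned = AlignedRaster(hist_aligned, np.zeros(hist_aligned.shape, bool))
    hist = hist_aligned.codes
    code = category.value
    was = hist == code
    now_effective = np.where(hist_aligned.aligned_stable, hist, contemp) == code
    out = np.zeros(hist.shape, dtype=np.uint8)
    out[was & now_effective] = CHANGE_CODES["stable"]
    out[was & ~now_effective] = CHANGE_CODES["lost"]
    out[~was & now_effective] = CHANGE_CODES["gained"]
    return out


def flow_table(tm: TransitionMatrix) -> pd.DataFrame:
    """Long-form (from, to, area_km2, pct_of_area, pct_of_origin) flows.

    One row per non-zero from→to pair; ``pct_of_origin`` sums to 100 within
    each origin category.
    """
    total = tm.n_cells
    rows = []
    areas = tm.areas_km2
    row_sums = tm.counts.sum(axis=1)
    for frm in tm.counts.index:
        origin = row_sums[frm]
        for to in tm.counts.columns:
            n = int(tm.counts.loc[frm, to])
            if n == 0:
                continue
            rows.append(
                {
                    "from": frm,
                    "to": to,
                    "cells": n,
                    "area_km2": float(areas.loc[frm, to]),
                    "pct_of_area": 100.0 * n / total if total else np.nan,
                    "pct_of_origin": 100.0 * n / origin if origin else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["from", "to", "cells", "area_km2",
                                       "pct_of_area", "pct_of_origin"])
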