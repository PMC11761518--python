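"""Point-grid accuracy assessment.

Extraction quality is assessed on a regular point grid: each point carries
one or more visually observed categories (several when multiple occur within
the interpretation radius), the arbitrated extracted category at the point is
cross-tabulated against the observation, and per-category false-positive /
false-negative percentages plus the overall accuracy are derived from the
table.  A multi-label point counts as correctly classified when the extracted
category is any of its observed categories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .categories import DEFAULT_PRIORITY, Category
from .geo_io import CategoryLayer

__all__ = [
    "ValidationPoint",
    "CrossTab",
    "generate_grid",
    "cross_tabulate",
    "accuracy_metrics",
    "read_points_csv",
    "write_points_csv",
]

#: Table row/column order: the five targets then the catch-all.
TABLE_ORDER: tuple[Category, ...] = (
    Category.forest,
    Category.wetland,
    Category.heath,
    Category.dune_sand,
    Category.water_body,
    Category.other,
)


@dataclass
class ValidationPoint:
    id: int
    x: float
    y: float
    observed: list[Category] = field(default_factory=list)
    radius_m: float = 50.0


@dataclass
class CrossTab:
    """Extracted-vs-observed count table with explicit margins.

    Normally built from per-point counts (margins are then the sums); it can
    also be built directly from published margins
    (:meth:`from_margins`), in which case the stored row/column totals are
    authoritative and the grand total is the sum of the row totals.
    """

    counts: pd.DataFrame           # index = extracted, columns = observed
    row_totals: pd.Series
    col_totals: pd.Series
    grand_total: int

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CrossTab":
        counts = counts.astype(int)
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        return cls(
            counts=counts,
            row_totals=counts.sum(axis=1),
            col_totals=counts.sum(axis=0),
            grand_total=int(counts.values.sum()),
        )

    @classmethod
    def from_margins(
        cls,
        categories: list[str],
        diagonal: list[int],
        row_totals: list[int],
        col_totals: list[int],
    ) -> "CrossTab":
        """Rebuild a table from published diagonal and marginal totals.

        Off-diagonal cells are unknowable from margins alone and are left
        zero; the margins are stored as given (published tables are not
        always internally consistent to the last count).
        """
        counts = pd.DataFrame(
            np.diag(diagonal), index=categories, columns=categories
        )
        rows = pd.Series(row_totals, index=categories)
        cols = pd.Series(col_totals, index=categories)
        if ((rows < counts.values.diagonal()) | (cols < counts.values.diagonal())).any():
            raise ValueError("diagonal exceeds a marginal total")
        return cls(counts=counts, row_totals=rows, col_totals=cols,
                   grand_total=int(rows.sum()))

    @property
    def categories(self) -> list[str]:
        return list(self.counts.index)


def generate_grid(
    aoi: Polygon,
    spacing_m: float = 100.0,
    start_id: int = 1,
) -> list[ValidationPoint]:
    """Regular point grid with the given equidistance, clipped to the AOI.

    Points sit at (xmin + spacing/2 + i·spacing, ymin + spacing/2 + j·spacing)
    and are returned row-major from the north-west corner.
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    if aoi.is_empty:
        return []
    xmin, ymin, xmax, ymax = aoi.bounds
    xs = np.arange(xmin + spacing_m / 2, xmax, spacing_m)
    ys = np.arange(ymin + spacing_m / 2, ymax, spacing_m)
    if len(xs) == 0 or len(ys) == 0:
        return []
    shapely.prepare(aoi)
    pts = []
    pid = start_id
    for y in ys[::-1]:  # row-major from the top
        inside = shapely.contains_xy(aoi, xs, np.full_like(xs, y))
        for x, ok in zip(xs, inside):
            if ok:
                pts.append(ValidationPoint(id=pid, x=float(x), y=float(y)))
                pid += 1
    return pts


def _arbitrate(
    layers: dict[Category, CategoryLayer],
    points: list[ValidationPoint],
    priority: tuple[Category, ...],
) -> list[Category]:
    """Extracted category per point under the fixed overlap priority."""
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    extracted = [Category.other] * len(points)
    claimed = np.zeros(len(points), dtype=bool)
    for cat in priority:
        layer = layers.get(cat)
        if layer is None or not layer.polygons:
            continue
        geom = layer.union()
        shapely.prepare(geom)
        hit = shapely.intersects_xy(geom, xs, ys) & ~claimed
        for i in np.nonzero(hit)[0]:
            extracted[i] = cat
        claimed |= hit
    return extracted


def cross_tabulate(
    layers: dict[Category, CategoryLayer] | list[CategoryLayer],
    points: list[ValidationPoint],
    priority: tuple[Category, ...] = DEFAULT_PRIORITY,
) -> CrossTab:
    """Cross-tabulate arbitrated extraction against labelled points.

    The observed column is the extracted category when it matches any
    observed label (a multi-label point counts as correct on any match);
    otherwise the first-listed observed category.  Points outside all layers
    count as extracted ``other``.
    """
    if isinstance(layers, list):
        layers = {l.category: l for l in layers}
    for p in points:
        if not p.observed:
            raise ValueError(f"point {p.id} has no observed categories")
    names = [c.name for c in TABLE_ORDER]
    counts = pd.DataFrame(0, index=names, columns=names)
    extracted = _arbitrate(layers, points, priority)
    for p, e in zip(points, extracted):
        observed = [o if o in TABLE_ORDER else Category.other for o in p.observed]
        o = e if e in observed else observed[0]
        counts.loc[e.name, o.name] += 1
    return CrossTab.from_counts(counts)


def _round1(value: float) -> float:
    """Round to one decimal, half away from zero (tabular convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def accuracy_metrics(ct: CrossTab) -> dict:
    """Per-category FP%, FN% and overall accuracy from a cross-table.

    FP%(c) = 100·(rowtotal − diagonal)/rowtotal (commission),
    FN%(c) = 100·(coltotal − diagonal)/coltotal (omission),
    overall% = 100·Σ diagonal / grand total; all to one decimal, half-up.
    Categories with a zero margin report no metric (absent, not 0).
    """
    fp: dict[str, float] = {}
    fn: dict[str, float] = {}
    diag_sum = 0
    for cat in ct.categories:
        d = int(ct.counts.loc[cat, cat])
        diag_sum += d
        rt = int(ct.row_totals[cat])
        cl = int(ct.col_totals[cat])
        if rt > 0:
            fp[cat] = _round1(100.0 * (rt - d) / rt)
        if cl > 0:
            fn[cat] = _round1(100.0 * (cl - d) / cl)
    overall = (
        _round1(100.0 * diag_sum / ct.grand_total) if ct.grand_total > 0 else None
    )
    return {"false_positive_pct": fp, "false_negative_pct": fn,
            "overall_accuracy_pct": overall}


def write_points_csv(points: list[ValidationPoint], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "observed"])
        for p in points:
            w.writerow([p.id, p.x, p.y, "|".join(c.name for c in p.observed)])


def read_points_csv(path) -> list[ValidationPoint]:
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            observed = [
                Category[name] for name in row["observed"].split("|") if name
            ]
            points.append(
                ValidationPoint(
                    id=int(row["id"]), x=float(row["x"]), y=float(row["y"]),
                    observed=observed,
                )
            )
    return points
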