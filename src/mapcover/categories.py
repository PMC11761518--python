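"""Land-use/land-cover category vocabulary.

The vocabulary covers both the historical map (five extraction targets plus a
catch-all) and the contemporary categorical raster (which additionally maps dry
grassland, agriculture and built-up land).  Integer codes are stable and are
used in every categorical raster the package reads or writes.
"""

from __future__ import annotations

import enum


class Category(enum.Enum):
    """LULC category codes shared by historical and contemporary layers."""

    forest = 1
    wetland = 2
    heath = 3
    dune_sand = 4
    water_body = 5
    dry_grassland = 6
    agriculture = 7
    built_up = 8
    other = 9

    def __str__(self) -> str:  # CSV / CLI friendly
        return self.name


#: The five categories extracted from the historical sheets.
TARGET_CATEGORIES: tuple[Category, ...] = (
    Category.forest,
    Category.wetland,
    Category.heath,
    Category.dune_sand,
    Category.water_body,
)

#: Arbitration order when extracted layers overlap (most reliable first).
DEFAULT_PRIORITY: tuple[Category, ...] = (
    Category.water_body,
    Category.forest,
    Category.wetland,
    Category.heath,
    Category.dune_sand,
)

#: Display colours for categorical GeoTIFF colour tables (r, g, b).
CATEGORY_COLOURS: dict[Category, tuple[int, int, int]] = {
    Category.forest: (44, 118, 50),
    Category.wetland: (120, 180, 210),
    Category.heath: (186, 96, 146),
    Category.dune_sand: (235, 214, 138),
    Category.water_body: (42, 80, 190),
    Category.dry_grassland: (196, 212, 110),
    Category.agriculture: (242, 238, 188),
    Category.built_up: (120, 120, 120),
    Category.other: (225, 225, 225),
}


def category_from_name(name: str) -> Category:
    """Resolve a category from its name, tolerating spaces and case."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return Category[key]
    except KeyError as exc:
        raise ValueError(f"unknown LULC category: {name!r}") from exc
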