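"""Programmatic cartographic symbol glyphs.

Wetland and heath carry distinct point symbols on the historical sheets
(wetland: short horizontal double bars; heath: a small plant "tuft").  The
same glyph rasters serve both as the default matched templates of the symbol
detector and as the stamps of the synthetic scene generator.
"""

from __future__ import annotations

import numpy as np

from .categories import Category

__all__ = ["wetland_glyph", "heath_glyph", "default_glyphs"]


def wetland_glyph() -> np.ndarray:
    """Three staggered horizontal marsh dashes, the wetland signature.

    Each dash is 2 px tall and ≥ 9 px wide, so dashes are too elongated
    (compactness < 0.5) to be mistaken for stipple dots.
    """
    g = np.zeros((8, 21), dtype=bool)
    g[0:2, 5:16] = True
    g[6:8, 0:9] = True
    g[6:8, 12:21] = True
    return g


def heath_glyph() -> np.ndarray:
    """A three-stroke plant tuft rising from a base point, the heath signature."""
    g = np.zeros((9, 9), dtype=bool)
    g[2:9, 4] = True          # stem
    for i in range(5):        # diverging side strokes (4-connected staircases)
        g[6 - i, 2 - i // 2] = True
        g[7 - i, 2 - i // 2] = True
        g[6 - i, 6 + i // 2] = True
        g[7 - i, 6 + i // 2] = True
    g[8, 3:6] = True          # base
    return g


def default_glyphs() -> dict[Category, np.ndarray]:
    return {Category.wetland: wetland_glyph(), Category.heath: heath_glyph()}
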