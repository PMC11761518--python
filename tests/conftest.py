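import numpy as np
import pytest

from mapcover.extract_colour import PipelineConfig, SheetContext
from mapcover.synthmap import SceneSpec, make_scene


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = float(np.logical_or(a, b).sum())
    return float(np.logical_and(a, b).sum()) / union if union else 1.0


@pytest.fixture(scope="session")
def small_scene():
    """An 800 m x 800 m scene shared across tests.

    Symbol density is raised above the default so that even this small extent
    carries enough wetland/heath symbols for per-sheet rule selection.
    """
    return make_scene(SceneSpec(extent_m=800.0, seed=5,
                                symbol_density_per_km2=150.0))


@pytest.fixture(scope="session")
def small_ctx(small_scene):
    return SheetContext(small_scene.rgb, PipelineConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
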