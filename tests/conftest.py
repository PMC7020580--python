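import numpy as np
import pytest

import toponome as tp
from toponome import synthetic as syn


@pytest.fixture(scope="session")
def small_panel():
    return tp.MarkerPanel(("a", "b", "c", "d"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_cmp_map(rng, shape=(64, 64), n_markers=13, density=0.6, panel=None):
    """Random code map with a controlled background fraction."""
    panel = panel or tp.DEFAULT_PANEL
    codes = rng.integers(0, 1 << n_markers, size=shape)
    codes[rng.random(shape) > density] = 0
    return tp.CMPMap(codes=codes, panel=panel)


@pytest.fixture(scope="session")
def demo_scene():
    """Small single-subject scene shared across tests."""
    scene = syn.generate_scene(
        {"s1": "KO"},
        {"KO": {"A": 0.6, "B": 0.4}},
        n_cells_per_subject=6,
        width=256,
        height=256,
        seed=7,
    )
    profiles = syn.default_profiles()
    gray, truth = syn.render_marker_stack(scene, profiles)
    return scene, gray, truth


@pytest.fixture(scope="session")
def demo_binary_stack(demo_scene):
    scene, gray, truth = demo_scene
    return tp.prepare_stack(
        gray, tp.DEFAULT_PANEL, thresholds=[syn.DEFAULT_THRESHOLD] * 13,
        margin=15, max_shift=6,
    )
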