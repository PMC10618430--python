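import numpy as np
import pytest

from pnpmetrics import synth


@pytest.fixture(scope="session")
def sheet_scene():
    """Default noisy sheet scene, shared across tests (read-only)."""
    params = synth.SceneParams(seed=1)
    stack, truth = synth.make_sheet_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def quiet_sheet_scene():
    """Noise-free sheet scene for exact segmentation checks."""
    params = synth.SceneParams(seed=2, noise_sigma=0.0)
    stack, truth = synth.make_sheet_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def geometry_scene():
    params = synth.SceneParams(seed=5)
    stack, truth = synth.make_geometry_scene(params)
    return params, stack, truth

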