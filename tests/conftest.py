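import numpy as np
import pytest

from hsrskit import (
    SceneParams,
    UnmixConfig,
    default_references,
    generate_scene,
    render_stack,
    unmix_stack,
)


@pytest.fixture(scope="session")
def refs():
    return default_references()


@pytest.fixture(scope="session")
def dense_scene():
    """Small scene where every cell carries an aggregate (fast, high signal)."""
    params = SceneParams(
        image_shape=(256, 256), n_cells=20, aggregate_probability=1.0, seed=1
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def noiseless_render(dense_scene, refs):
    return render_stack(dense_scene, refs, noise_sigma=0.0, seed=2)


@pytest.fixture(scope="session")
def noisy_render(dense_scene, refs):
    """Default-noise rendering of the dense scene."""
    return render_stack(dense_scene, refs, seed=3)


@pytest.fixture(scope="session")
def noisy_maps(noisy_render, refs):
    stack, _ = noisy_render
    return unmix_stack(stack, refs, UnmixConfig(lam=0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
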