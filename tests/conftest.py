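import numpy as np
import pytest

from dapicyto.synthetic import (
    ComponentSpec,
    SyntheticSceneSpec,
    render_scene,
    stage_presets,
    suggest_shape,
)


@pytest.fixture(scope="session")
def presets():
    return stage_presets()


def make_scene_spec(
    components,
    n_standard=10,
    seed=0,
    noise_sd=2.0,
    **overrides,
):
    spec = SyntheticSceneSpec(
        components=components,
        n_standard=n_standard,
        seed=seed,
        noise_sd=noise_sd,
        **overrides,
    )
    spec.image_shape = suggest_shape(spec)
    return spec


@pytest.fixture(scope="session")
def small_scene():
    """30 zoospore-like nuclei + 10 standards, rendered once per session."""
    spec = make_scene_spec(
        [ComponentSpec("zoospore", 0.76, 0.09, 30)], n_standard=10, seed=5
    )
    image, gt = render_scene(spec)
    return spec, image, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
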