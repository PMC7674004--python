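import numpy as np
import pytest

from octamls import (
    CohortEffectSpec,
    PhantomConfig,
    generate_cohort_feature_table,
    generate_layer_stack,
    generate_panomap,
)


@pytest.fixture(scope="session")
def uniform_cfg():
    """Noise-free phantom: uniform background 100, no vessel tree."""
    return PhantomConfig(noise_sd=0.0, background_intensity=100.0, macro_tree=None, seed=1)


@pytest.fixture(scope="session")
def uniform_stack(uniform_cfg):
    return generate_layer_stack(uniform_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    """Realistic phantom: default backgrounds, vessel tree, mild noise."""
    return PhantomConfig(seed=7, fovea_disc_angle_deg=6.0)


@pytest.fixture(scope="session")
def default_stack(default_cfg):
    return generate_layer_stack(default_cfg)


@pytest.fixture(scope="session")
def default_panomap(default_cfg):
    return generate_panomap(default_cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-level cohort with the default severity effect, 20+20."""
    spec = CohortEffectSpec(n_per_group={"control": 20, "glaucoma": 20}, seed=11)
    return generate_cohort_feature_table(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
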