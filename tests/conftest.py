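import numpy as np
import pytest

from phasestates import GeneratorConfig, make_latent_states, make_bold
from phasestates.phase import vector_from_matrix


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def template_vectors(default_config) -> np.ndarray:
    """K x D vectorized coherence templates of the default generator."""
    return np.array([vector_from_matrix(t) for t in default_config.state_templates])


@pytest.fixture(scope="session")
def small_rest_runs(default_config):
    """A few default-condition resting-state runs with their latent truth."""
    runs = []
    for s in range(3):
        lat = make_latent_states(default_config, 600, 300 + s)
        ts = make_bold(lat, default_config, 400 + s, subject_id=f"sub-{s + 1:02d}")
        runs.append((lat, ts))
    return runs
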