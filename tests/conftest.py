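import pytest

from gridmech.synthetic_data import GeneratorConfig, JunctionConfig, TopographyConfig


@pytest.fixture
def quiet_cfg():
    """Noise-free force-curve generator config."""
    return GeneratorConfig(seed=0, noise_sd=0.0, periodic_noise=[])


@pytest.fixture
def noisy_cfg():
    """Generator config with Gaussian + mains-harmonic noise."""
    return GeneratorConfig(seed=7, noise_sd=0.3)


@pytest.fixture
def flat_topo_cfg():
    """Noise-free topography config (exact plateaus, ideal boundary)."""
    return TopographyConfig(seed=0)


@pytest.fixture
def smooth_junction_cfg():
    """Roughness-free junction config (parallel plane membranes)."""
    return JunctionConfig(seed=0, membrane_roughness=0.0)
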