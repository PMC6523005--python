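import numpy as np
import pytest

from radqc import beam_sim


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Full-protocol simulated experiment with zero measurement noise."""
    protocol = beam_sim.TransmissionProtocol(noise_cv=0.0, seed=11)
    return beam_sim.simulate_transmission_experiment(protocol)


@pytest.fixture(scope="session")
def default_spectra():
    return beam_sim.default_spectra()


@pytest.fixture()
def offset_scene():
    """Noiseless scene with the source foot away from the platform center."""
    config = beam_sim.SceneConfig(source_foot=(12.3, -4.5), sid=1000.0)
    observations, truth = beam_sim.simulate_scene(config)
    return config, observations, truth


def random_scene_config(rng: np.random.Generator, noise_sd: float = 0.0):
    """Draw a physically plausible random scene configuration."""
    return beam_sim.SceneConfig(
        source_foot=tuple(rng.uniform(-40.0, 40.0, 2)),
        sid=float(rng.uniform(800.0, 1500.0)),
        platform_center=tuple(rng.uniform(-30.0, 30.0, 2)),
        platform_half_width=50.0,
        platform_height=200.0,
        bottom_marker_height=2.0,
        localization_noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
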