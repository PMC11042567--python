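import numpy as np
import pytest

from fnirsdep.simulate import CohortSpec, NoiseProfile, TaskParadigm, \
    simulate_cohort


@pytest.fixture(scope="session")
def paradigm():
    return TaskParadigm()


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 subjects, 4 channels: quick fixture for pipeline plumbing."""
    spec = CohortSpec(n_severe=4, n_mild=4, n_channels=4, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def inband_noise_profile():
    """Residual in-band noise (cardiac + broadband) as left after the
    drift/motion stages; this is what the decomposition denoisers target."""
    return NoiseProfile(cardiac_amp=0.25, resp_amp=0.0, drift_amp=0.0,
                        white_sigma=0.15, artifact_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
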