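import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, database=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

REDUCED_SIZES = (8, 4, 4, 4, 8, 4, 4, 4)  # scaled-down structural ensembles


def random_state(rng, n_neurons, n_timesteps, n_ensembles):
    """A random valid (t, omega, s) triple."""
    t = rng.dirichlet(np.ones(n_ensembles), size=n_neurons).T
    omega = rng.random((n_timesteps, n_ensembles))
    s = rng.random((n_neurons, n_timesteps))
    return t, omega, s


def random_binary_state(rng, n_neurons, n_timesteps, n_ensembles):
    """A random one-hot/binary (t, omega, s) triple (the hard baseline)."""
    labels = rng.integers(n_ensembles, size=n_neurons)
    t = np.zeros((n_ensembles, n_neurons))
    t[labels, np.arange(n_neurons)] = 1.0
    omega = rng.integers(2, size=(n_timesteps, n_ensembles)).astype(float)
    s = rng.integers(2, size=(n_neurons, n_timesteps)).astype(float)
    return t, omega, s


@pytest.fixture(scope="session")
def scenario3_reduced():
    """One fixed reduced scenario-3 synthetic dataset (N=40, M=500)."""
    from neuroensemble.synthetic import generate_dataset

    return generate_dataset(3, sizes=REDUCED_SIZES, n_frames=500, rng=42)
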