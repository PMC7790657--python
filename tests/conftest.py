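import dataclasses

import numpy as np
import pytest

import heterodeb as hd
from heterodeb.population import MortalityModel


@pytest.fixture(scope="session")
def params() -> hd.DEBParams:
    return hd.default_params()


@pytest.fixture(scope="session")
def env():
    return hd.baseline_environment()


@pytest.fixture(scope="session")
def meanfield_config() -> hd.PopulationConfig:
    """Deterministic single-individual configuration (no TB scatter)."""
    return hd.PopulationConfig(
        n_individuals=1, n_replicates=1, seed=0,
        scatter=hd.ScatterConfig(cv_normotherm=0.0, cv_heterotherm=0.0))


@pytest.fixture(scope="session")
def small_config() -> hd.PopulationConfig:
    """Reduced cohort for fast stochastic checks."""
    return hd.PopulationConfig(n_individuals=10, n_replicates=5, seed=7)


@pytest.fixture(scope="session")
def baseline_result(params, env):
    """Full paired baseline experiment (25 x 25 per group, mortality on)."""
    config = hd.PopulationConfig(seed=20201122)
    return hd.run_experiment(config, params, env, MortalityModel())


def meanfield_replicate(params, env, config, mortality=None, **overrides):
    """One deterministic replicate of both groups; helper used across tests."""
    config = dataclasses.replace(config, **overrides) if overrides else config
    rng = np.random.default_rng(0)
    return hd.run_replicate(config, params, env, rng,
                            mortality or MortalityModel(pmax=0.0))
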