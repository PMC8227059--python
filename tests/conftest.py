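import numpy as np
import pandas as pd
import pytest

from hybridgp import kinship, simulate, trial


@pytest.fixture(scope="session")
def small_study():
    """Four-population study at reduced scale, shared across read-only tests."""
    cfg = simulate.default_config(
        n_markers=400,
        seed=5,
        n_lines=(60, 50, 50, 50),
        n_qtl=100,
        var_g=1600.0,
        var_ge=900.0,
        var_rep=50.0,
        var_error=900.0,
    )
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_blues(small_study):
    return trial.fit_blue(small_study.records, scope="across_env").series()


@pytest.fixture(scope="session")
def small_kinships(small_study):
    Ka = kinship.additive_kinship(small_study.hybrids.Z)
    Kd = kinship.dominance_kinship(small_study.hybrids.W)
    return Ka, Kd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_codes(rng, n_lines, n_markers, index_prefix="h"):
    """Random hybrid-style additive codes in {-1, -0.5, 0, 0.5, 1}."""
    vals = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=(n_lines, n_markers))
    return pd.DataFrame(vals, index=[f"{index_prefix}{i}" for i in range(n_lines)])
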