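import numpy as np
import pandas as pd
import pytest

from suitsurv import (
    EnvFieldSpec,
    EnvGridStack,
    GridTransform,
    VirtualSpeciesSpec,
    gen_env_stack,
    gen_true_suitability,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def env_small():
    """60x60 planar-km stack, 3 moderately autocorrelated layers."""
    return gen_env_stack(EnvFieldSpec(
        n_layers=3, grid_shape=(60, 60), cell_size=1.0,
        autocorr_range=8.0, seed=42))


@pytest.fixture(scope="session")
def virtual_world():
    """A 100x100 world with a Gaussian-niche species and its occurrences."""
    env = gen_env_stack(EnvFieldSpec(
        n_layers=3, grid_shape=(100, 100), cell_size=1.0,
        autocorr_range=15.0, seed=7))
    spec = VirtualSpeciesSpec(optima=[0.8, -0.5, 0.0],
                              breadths=[0.8, 1.0, 1.2],
                              n_occurrences=300, seed=8, name="vsp")
    suit = gen_true_suitability(env, spec)
    occ = sample_occurrences(suit, env, spec)
    return {"env": env, "spec": spec, "suitability": suit, "occ": occ}


@pytest.fixture(scope="session")
def table1_long():
    """Long-form view of the packaged garden survival-rate table."""
    from suitsurv.survival import fixture_sr_long
    return fixture_sr_long()


@pytest.fixture()
def tiny_grid():
    """2x2 single-layer grid with values 0..3 (row-major)."""
    return EnvGridStack({"env1": np.array([[0.0, 1.0], [2.0, 3.0]])},
                        GridTransform(0.0, 2.0, 1.0, 1.0))


def make_occ(points, species="sp", source="test"):
    """Occurrence table from a list of (lon, lat)."""
    return pd.DataFrame({
        "species": species,
        "lon": [p[0] for p in points],
        "lat": [p[1] for p in points],
        "source": source,
    })
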