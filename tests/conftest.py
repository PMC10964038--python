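import numpy as np
import pandas as pd
import pytest

from morphotx.config import RunConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_config():
    """A fast simulation: 40 regions, 12+10 subjects, 60 genes."""
    return SimulationConfig(
        n_regions=40,
        n_pd=12,
        n_hc=10,
        n_genes=60,
        n_causal_genes=6,
        n_effect_regions=10,
        cell_set_size=12,
        seed=7,
    )


@pytest.fixture
def tiny_run_config(tiny_config):
    return RunConfig(
        simulation=tiny_config, n_rotations=99, n_boot=100, n_perm=200, seed=7
    )


@pytest.fixture
def random_features(rng):
    """A 20-region x 7-feature table with no degenerate columns."""
    values = rng.standard_normal((20, 7))
    return pd.DataFrame(
        values,
        index=[f"R{i:03d}" for i in range(20)],
        columns=list("ABCDEFG"),
    )
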