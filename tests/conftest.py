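import numpy as np
import pytest

import knockvimp as kv


@pytest.fixture(scope="session")
def bias_small():
    """A small correlated-null dataset shared by fast tests."""
    return kv.make_bias_scenario(
        n=300, rho=0.7, betas=(1.0, 1.0), prevalence=0.3, n_noise=2, seed=11
    )


@pytest.fixture(scope="session")
def tiny_forest_data():
    """n=30, p=4 toy problem plus a 3-tree forest (oracle-sized)."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((30, 4))
    y = (rng.random(30) < 0.4).astype(int)
    forest = kv.BootstrapForest(
        n_trees=3, mtry=2, min_node_size=2, mode="classification", random_state=5
    ).fit(X, y)
    return forest, X, y
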