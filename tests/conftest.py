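import numpy as np
import pytest

from polyamine_builder import (
    GrowthConfig,
    default_param_table,
    grow_polymer,
)


@pytest.fixture(scope="session")
def param_table():
    """Placeholder bonded-parameter table covering every PEI type."""
    return default_param_table()


@pytest.fixture(scope="session")
def random_polymers():
    """A reusable batch of small random complete polymers (varied targets)."""
    rng = np.random.default_rng(20240)
    graphs = []
    for i in range(60):
        mw = float(rng.uniform(400, 2500))
        db = float(rng.uniform(0.2, 0.8))
        cfg = GrowthConfig(target_mw=mw, target_db=db, p_term=0.05, seed=1000 + i)
        graphs.append(grow_polymer(cfg))
    return graphs
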