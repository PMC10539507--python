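import numpy as np
import pandas as pd
import pytest

import invasiotype as iv


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_expr():
    """5 genes x 4 samples with distinct values."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.normal(7, 1, size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )


@pytest.fixture
def small_config():
    """Desk-scale cohort small enough for per-test simulation."""
    return iv.SimulationConfig(
        n_genes=2000, n_tfs=20, sets_per_tf=2, targets_per_set=15,
        target_overlap=0.2, n_low=6, n_high=6, effect_size=1.5,
        n_promoting=2, n_suppressing=1, seed=11,
    )


@pytest.fixture
def small_cohort(small_config):
    regulons, truth = iv.generate_regulons(small_config)
    expr, phen = iv.generate_expression(small_config, regulons, truth)
    return small_config, regulons, truth, expr, phen
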