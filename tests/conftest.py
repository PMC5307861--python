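import numpy as np
import pandas as pd
import pytest

from lncpop import ExpressionMatrix, SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation: 60 lncRNAs + 90 mRNAs, 20 individuals/env."""
    return SimulationConfig(
        n_lncRNA=60, n_mRNA=90, n_individuals_per_env=20,
        n_modules_shared=1, n_modules_env_specific=2,
        module_size_lncRNA=3, module_size_mRNA=4,
        n_trait_genes=3, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_expression(small_config)


def toy_matrix(values, classes, envs):
    """Hand-built ExpressionMatrix from plain nested lists."""
    n_feat = len(values)
    n_ind = len(values[0])
    feats = [f"f{i}" for i in range(n_feat)]
    inds = [f"i{j}" for j in range(n_ind)]
    return ExpressionMatrix(
        values=pd.DataFrame(np.asarray(values, dtype=float),
                            index=feats, columns=inds),
        feature_class=pd.Series(classes, index=feats),
        environment=pd.Series(envs, index=inds),
    )
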