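import numpy as np
import pytest

from foldcep import (
    FoldClassificationModel,
    continuum_config,
    discrete_config,
    generate_universe,
)


@pytest.fixture(scope="session")
def discrete_universe():
    """A completely discrete synthetic fold space (known truth)."""
    return generate_universe(discrete_config(seed=4))


@pytest.fixture(scope="session")
def continuum_universe():
    """A fold space with a heterogeneity gradient and bridge domains."""
    return generate_universe(continuum_config(seed=2))


@pytest.fixture(scope="session")
def continuum_cep_results(continuum_universe):
    """Leave-one-out CEP classification of every continuum-universe domain."""
    table, local, _, _ = continuum_universe
    model = FoldClassificationModel(table, local, min_fold_size=25)
    res = model.fit(methods=("tm_max", "cep"))
    return res, res.classify_members()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
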