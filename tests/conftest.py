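import numpy as np
import pytest

from pseudoipd import (LMMSpec, fit_lmm, generate_pseudo_ipd, load_fixture,
                       model_grid)


@pytest.fixture(scope="session")
def iron():
    return load_fixture("iron")


@pytest.fixture(scope="session")
def folate():
    return load_fixture("folate")


@pytest.fixture(scope="session")
def iron_pipd(iron):
    return generate_pseudo_ipd(iron, method="two_point")


@pytest.fixture(scope="session")
def folate_pipd(folate):
    return generate_pseudo_ipd(folate, method="two_point")


@pytest.fixture(scope="session")
def iron_grid_reml(iron_pipd):
    """All 12 models on the iron pseudo IPD, REML estimates."""
    return model_grid(iron_pipd, estimation="REML")


def grid_fit(grid, effects, residual):
    row = grid[(grid["effects"] == effects) & (grid["residual"] == residual)]
    fit = row["fit"].iloc[0]
    assert fit is not None, row["error"].iloc[0]
    return fit


@pytest.fixture(scope="session")
def folate_fr_free(folate_pipd):
    return fit_lmm(folate_pipd,
                   LMMSpec(effects="FR", residual="FREE", estimation="REML"))


@pytest.fixture
def rng():
    return np.random.default_rng(20190108)
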