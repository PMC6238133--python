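import numpy as np
import pytest

import survmeta as sm


@pytest.fixture(scope="session")
def master_params():
    """Phocid-scale RAW parameters (posterior-mean magnitude)."""
    return sm.RAWParams(a=0.05402, b=2.6067, c=0.0057)


@pytest.fixture(scope="session")
def fixture_collection():
    col, truth = sm.phocid_fixture()
    return col, truth


@pytest.fixture(scope="session")
def fixture_fit(fixture_collection):
    """One shared full-length fit of the species+dataset model on the
    packaged synthetic fixture; reused by prediction/diagnostic tests."""
    col, truth = fixture_collection
    model = sm.NaturalMortalityModel(col, spec="~master + species + dataset")
    res = model.fit(n_chains=3, n_iter=15_000, burn_in=5_000, thin=10, seed=7)
    return res, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
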