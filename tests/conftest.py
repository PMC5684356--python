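import numpy as np
import pytest

from glyconet.pathway import default_rules, known_pathway


@pytest.fixture(scope="session")
def known():
    return known_pathway()


@pytest.fixture(scope="session")
def rules():
    return {r.id: r for r in default_rules()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)
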