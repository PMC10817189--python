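import numpy as np
import pytest

from cregrammar.tfbs_library import make_alphabet


@pytest.fixture(scope="session")
def crx_nrl_alphabet():
    return make_alphabet("crx_nrl")


@pytest.fixture(scope="session")
def cdnrm_alphabet():
    return make_alphabet("cdnrm")


@pytest.fixture(scope="session")
def crx_nrl_benchmark():
    """Shared library-shaped synthetic benchmark (1,299 CREs, pairwise truth)."""
    from cregrammar.synthetic_data import make_benchmark

    return make_benchmark("crx_nrl_like", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
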