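import numpy as np
import pytest

from humanrand.ctm import load_ctm_table


@pytest.fixture(scope="session")
def table():
    """The packaged complexity table (loaded once; read-only)."""
    return load_ctm_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


def random_binary(rng, n):
    return "".join("01"[b] for b in rng.integers(0, 2, n))
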