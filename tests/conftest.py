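import numpy as np
import pytest

from burstnet.approx import cube_table, square_table, exp_table


@pytest.fixture(scope="session")
def tables():
    return {"cube": cube_table(), "square": square_table(),
            "exp": exp_table()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
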