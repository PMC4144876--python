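import logging

import numpy as np
import pandas as pd
import pytest

from methfidelity.io import BetaMatrix

logging.getLogger("methfidelity").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20140826)


@pytest.fixture
def small_beta(rng):
    """A complete 20-probe x 6-sample beta matrix."""
    values = pd.DataFrame(
        rng.random((20, 6)),
        index=[f"cg{i:04d}" for i in range(20)],
        columns=[f"S{j}" for j in range(6)],
    )
    return BetaMatrix(values)


@pytest.fixture
def beta_with_missing(rng):
    arr = rng.random((10, 5))
    arr[0, 0] = np.nan
    arr[3, 2] = np.nan
    arr[3, 3] = np.nan
    values = pd.DataFrame(
        arr,
        index=[f"cg{i:04d}" for i in range(10)],
        columns=[f"S{j}" for j in range(5)],
    )
    return BetaMatrix(values)
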