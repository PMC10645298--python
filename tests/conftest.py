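import numpy as np
import pytest

from hltexpd.datasets import load_dataset


@pytest.fixture(scope="session")
def kevlar():
    return load_dataset("kevlar76").values


@pytest.fixture(scope="session")
def guinea():
    return load_dataset("guinea72").values


@pytest.fixture(scope="session")
def bearings():
    return load_dataset("bearings23").values


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230992)
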