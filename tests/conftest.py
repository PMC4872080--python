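import numpy as np
import pytest

from ptrmap.config import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    return RunConfig(seed=11)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
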