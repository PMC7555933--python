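import numpy as np
import pytest

from miredit import (
    MirnaReference,
    SampleDesign,
    SimParams,
    gen_reference,
    gen_truth,
)


@pytest.fixture(scope="session")
def reference() -> MirnaReference:
    return gen_reference(10, (17, 24), seed=11)


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign.full_factorial(2)


@pytest.fixture(scope="session")
def truth(reference, design):
    return gen_truth(reference, design, SimParams(), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
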