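import numpy as np
import pytest

from nucleokin import DistributionParams, InductionDataset

#: reference truth used across tests: comparable to the 10 L series
REF_PARAMS = DistributionParams(J=0.1, t_g=10_000.0)
REF_VOLUME = 0.01  # m^3


@pytest.fixture
def ref_params():
    return REF_PARAMS


@pytest.fixture
def ref_volume():
    return REF_VOLUME


@pytest.fixture
def three_times_dataset():
    """The worked micro-example: three times, 10 mL... of a 0.01 m^3 vessel."""
    return InductionDataset("demo", (10_000.0, 11_000.0, 12_000.0), 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)
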