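import numpy as np
import pytest

from ssvepflow import (
    DoubleColumnParams,
    StimulusSpec,
    generate_inversion_fixture,
)


@pytest.fixture(scope="session")
def fixture_8hz():
    """A shared-noise double-column recording under 8 Hz flicker with known
    mid-box parameters; reused across inversion tests."""
    params = DoubleColumnParams(90.0, 85.0, 2200.0, 300.0)
    return generate_inversion_fixture(params, StimulusSpec(condition="8"), seed=11)


@pytest.fixture(scope="session")
def fixture_control():
    params = DoubleColumnParams(90.0, 85.0, 2200.0, 300.0)
    return generate_inversion_fixture(params, StimulusSpec(condition="control"), seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
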