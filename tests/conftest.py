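import warnings

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence routine pipeline warnings (empty-channel passthrough etc.)
    so tests fail only on real problems."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
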