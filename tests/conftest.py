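import numpy as np
import pytest

from internode import ClimateSeries, ModelConfig


@pytest.fixture
def constant_series():
    """Factory for a constant-climate series starting at day 1."""

    def make(n_days=40, par=375.0, temperature=20.0):
        return ClimateSeries(
            day=np.arange(1, n_days + 1),
            par=np.full(n_days, par),
            temperature=np.full(n_days, temperature),
        )

    return make


@pytest.fixture
def default_config():
    return ModelConfig()
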