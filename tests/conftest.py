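import pytest

from tlcval import simulate


@pytest.fixture
def noiseless_config():
    """Study conditions with the scanner noise switched off."""
    return simulate.study_config(seed=0, noise_sd=0.0)


@pytest.fixture
def study_cfg():
    return simulate.study_config(seed=123)
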