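import pytest

from spcpintron import simdata


@pytest.fixture(scope="session")
def long_dataset():
    """Default long-gene synthetic bundle (two introns on the clade stem)."""
    return simdata.emit_dataset(simdata.default_long_config(seed=11))


@pytest.fixture(scope="session")
def short_dataset():
    """Default short-gene bundle (one intron in a single tip)."""
    return simdata.emit_dataset(simdata.default_short_config(seed=11))
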