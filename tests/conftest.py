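import numpy as np
import pytest

from musicflow import ChannelPanel, default_panel
from musicflow.simulate import make_autofluorescence_endmember, make_endmember

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def panel():
    """Small 8-channel panel for fast unit tests."""
    return ChannelPanel(tuple(f"B{i}" for i in range(1, 9)))


@pytest.fixture
def full_panel():
    return default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio(full_panel):
    """Two single-dye endmembers plus their tandem combination, with AF."""
    a488 = make_endmember("Atto488", 1, full_panel, brightness_scale=1000.0)
    a647 = make_endmember("Atto647", 15, full_panel, brightness_scale=1000.0)
    combo = make_endmember(
        "Atto488_647", -1, full_panel, brightness_scale=1000.0,
        donor_acceptor_mix=0.5, parents=(a488, a647),
    )
    af = make_autofluorescence_endmember(full_panel)
    return [a488, a647, combo], af
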