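import numpy as np
import pytest

import transaural as ta
from transaural.design import DesignConfig
from transaural.plant import VA_PAIR


@pytest.fixture(scope="session")
def head():
    return ta.HeadModelSpec()


@pytest.fixture(scope="session")
def anechoic_plant(head):
    """Full six-source anechoic plant at the study geometry."""
    room, layout = ta.anechoic_preset()
    return ta.simulate_hadirs(head, room, layout)


@pytest.fixture(scope="session")
def anechoic_va(anechoic_plant):
    """The two-source (virtual-acoustics pair) design/evaluation plant."""
    return anechoic_plant.select_sources(VA_PAIR)


@pytest.fixture(scope="session")
def anechoic_results(anechoic_va):
    """Fitted inverse filters for the anechoic condition (beta = 0.0005)."""
    return ta.PressureMatchingModel(anechoic_va).fit()


@pytest.fixture(scope="session")
def booth_plant(head):
    room, layout = ta.booth_preset(seed=1)
    return ta.simulate_hadirs(head, room, layout, length=8192)


@pytest.fixture(scope="session")
def booth_results(booth_plant):
    return ta.PressureMatchingModel(
        booth_plant.select_sources(VA_PAIR),
        config=DesignConfig(beta=0.001),
        room="booth",
    ).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
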