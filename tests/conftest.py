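import pytest

from gemcarve.fixtures import (
    make_ambiguous_toy,
    make_crossfeed_pair,
    make_energy_cycle_toy,
    make_toy6,
)


@pytest.fixture
def toy6():
    """(model, score table, media) for the canonical toy universe."""
    return make_toy6()


@pytest.fixture
def toy6_model(toy6):
    return toy6[0]


@pytest.fixture
def toy6_scores(toy6):
    return toy6[1]


@pytest.fixture
def toy6_media(toy6):
    return toy6[2]


@pytest.fixture
def energy_cycle_toy():
    return make_energy_cycle_toy()


@pytest.fixture
def ambiguous_toy():
    return make_ambiguous_toy()


@pytest.fixture
def crossfeed_pair():
    return make_crossfeed_pair()
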