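import pytest

from xtalplan.presets import (
    LYSOZYME,
    LYSOZYME_C_S,
    LYSOZYME_HABIT,
    LYSOZYME_PEG4000_PARAMS,
)


@pytest.fixture(scope="session")
def lysozyme():
    """Lysozyme crystal-form spec (V_M 1.84 Å³/Da, MW 14300 Da)."""
    return LYSOZYME


@pytest.fixture(scope="session")
def bench_params():
    """Fitted kinetic constants for the lysozyme/NaCl/PEG4000 benchmark."""
    return LYSOZYME_PEG4000_PARAMS


@pytest.fixture(scope="session")
def bench_habit():
    return LYSOZYME_HABIT


@pytest.fixture(scope="session")
def bench_c_s():
    return LYSOZYME_C_S
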