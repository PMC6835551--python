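import pytest

from tojrace import (
    IndecisionParams,
    RaceParams,
    ResetParams,
    make_design,
)


@pytest.fixture(scope="session")
def exp1_design():
    return make_design("exp1")


@pytest.fixture(scope="session")
def asym_rates():
    """Unequal rates (60 vs 40 Hz), a typical well-trained observer."""
    return RaceParams(vp=0.06, vr=0.04)


@pytest.fixture(scope="session")
def sym_rates():
    return RaceParams(vp=0.05, vr=0.05)


@pytest.fixture(scope="session")
def typical_indecision(sym_rates):
    """Equal rates, 20 ms indecision half-width, neutral bias."""
    return IndecisionParams(rates=sym_rates, delta=20.0, xi=0.5, tau=0.0)


@pytest.fixture(scope="session")
def typical_reset(asym_rates):
    """Reset threshold 15 ms with 18 ms trial-by-trial spread."""
    return ResetParams(rates=asym_rates, t0=15.0, s0=18.0, tau=0.0)
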