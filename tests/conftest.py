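import numpy as np
import pytest

from talonmorph.talon import RadiationSpec, TalonParams, make_talon


@pytest.fixture(scope="session")
def default_talon():
    """Default-parameter talon at the standard demo resolution."""
    return make_talon(TalonParams(), (32, 16, 4))


@pytest.fixture(scope="session")
def coarse_talon():
    return make_talon(TalonParams(), (16, 12, 2))


@pytest.fixture(scope="session")
def small_radiation():
    """A 21-species radiation with landmarks at coarse mesh resolution."""
    from talonmorph.talon import simulate_radiation

    params, table, tree = simulate_radiation(RadiationSpec(seed=11))
    landmarks = []
    for sp in table["species"]:
        _, _, lm = make_talon(params[sp], (16, 12, 2))
        lm.specimen_id = sp
        landmarks.append(lm)
    return params, table, tree, landmarks


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
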