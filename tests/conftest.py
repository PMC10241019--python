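import math

import pandas as pd
import pytest

from alphadose.biodistribution import BiodistributionSeries
from alphadose.decay_chain import Branch, DecayChain, Nuclide, build_ac225_chain
from alphadose.dosimetry import Phantom, load_default_phantoms

DAY = 86400.0


@pytest.fixture(scope="session")
def ac225_chain():
    return build_ac225_chain()


@pytest.fixture(scope="session")
def toy_two_member_chain():
    """10-d alpha parent feeding a 46-min alpha daughter (then stable)."""
    parent = Nuclide(
        name="P", half_life=10 * DAY, mean_alpha_energy=5.0,
        branches=(Branch("D", 1.0, "alpha"),),
    )
    daughter = Nuclide(
        name="D", half_life=46 * 60.0, mean_alpha_energy=6.0,
        branches=(Branch("S", 1.0, "alpha"),),
    )
    stable = Nuclide(name="S", half_life=math.inf)
    return DecayChain(members=(parent, daughter, stable))


@pytest.fixture(scope="session")
def phantoms():
    return load_default_phantoms()


@pytest.fixture()
def single_organ_series():
    """Constant 10 %IA/g liver measured only at t = 0."""
    return BiodistributionSeries(
        pd.DataFrame(
            {"organ": ["liver"], "time_h": [0.0], "pct_ia_per_g": [10.0], "sd": [0.0], "n": [4]}
        )
    )


@pytest.fixture()
def minimal_phantom_pair():
    mouse = Phantom("mouse", 25.0, {"liver": 1.3, "kidney": 0.33})
    human = Phantom("human", 60000.0, {"liver": 1400.0, "kidney": 275.0})
    return mouse, human
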