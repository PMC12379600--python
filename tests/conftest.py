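import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from monofilm.monolayer import ContrastSpec, MonolayerParams, make_composition


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def dmpg_params():
    """DMPG monolayer in the solid phase (40 mN/m) with realistic hydration."""
    comp = make_composition("DMPG:1.0")
    return MonolayerParams(
        composition=comp, V_tail=668.0, d_tail=16.2, d_hg=8.0, sigma=4.2,
        headgroup_solvent_fraction=0.054,  # ~0.6 waters per lipid
    )


@pytest.fixture
def xray_contrast():
    return ContrastSpec(radiation="xray", subphase="water", label="xray")


@pytest.fixture
def neutron_contrasts():
    scen = {"DMPG": 2, "d54-DMPG": 2}
    return [
        ContrastSpec(radiation="neutron", subphase="D2O", exchange_scenario=scen, label="D2O"),
        ContrastSpec(radiation="neutron", subphase="ACMW", exchange_scenario=scen, label="ACMW"),
    ]
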