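import numpy as np
import pytest

from msystems.core import make_configuration, step
from msystems.mbac import build_mbac, preset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ecoli_params():
    return preset("ecoli")


@pytest.fixture(scope="session")
def adult_cell(ecoli_params):
    """One E. coli cell grown to adulthood (complete septum, one step
    before division) under unlimited nutrients, fixed seed."""
    sys = build_mbac(ecoli_params.injury_variant())
    cfg = make_configuration(sys)
    g = np.random.default_rng(11)
    for _ in range(200):
        step(cfg, sys, g)
        if sys.assembly.has_pending_division(cfg):
            break
    else:
        raise RuntimeError("cell never reached adulthood")
    return cfg, sys
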