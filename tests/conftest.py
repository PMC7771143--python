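import numpy as np
import pytest

import evosize as ez
from evosize.experiments import replace_config


@pytest.fixture(scope="session")
def phys():
    return ez.PhysiologyParams()


@pytest.fixture(scope="session")
def grid():
    return ez.make_grid()


@pytest.fixture(scope="session")
def paper9_cfg():
    """Calibrated 9-species community with evolution switched off."""
    from dataclasses import replace

    cfg = ez.make_fixture("paper9")
    return replace_config(cfg, evolution=replace(cfg.evolution, chi=0.0))


@pytest.fixture(scope="session")
def toy3_cfg():
    """Fast 3-species profile, evolution off."""
    from dataclasses import replace

    cfg = ez.make_fixture("toy3")
    return replace_config(cfg, evolution=replace(cfg.evolution, chi=0.0))


@pytest.fixture(scope="session")
def toy3_evo_cfg():
    """Fast 3-species profile with stochastic phenotype turnover."""
    return ez.make_fixture("toy3")


def fine_trapezoid(masses):
    w = np.empty_like(masses)
    w[1:-1] = 0.5 * (masses[2:] - masses[:-2])
    w[0] = 0.5 * (masses[1] - masses[0])
    w[-1] = 0.5 * (masses[-1] - masses[-2])
    return w
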