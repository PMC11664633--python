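import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import tvcox as tv


@pytest.fixture(scope="session")
def small_data():
    """n=60, p=2, continuous times (no ties), moderate censoring."""
    spec = tv.SimulationSpec(
        n=60,
        p=2,
        beta_funcs=(("constant", 0.5), ("sine", 1.0, 1.0)),
        censoring=("uniform", 6.0),
        t_horizon=3.0,
        seed=101,
    )
    data, _ = tv.simulate_dataset(spec)
    return data


@pytest.fixture(scope="session")
def tied_data():
    """n=80 with times rounded to 1 decimal: plenty of ties."""
    spec = tv.SimulationSpec(
        n=80,
        p=2,
        beta_funcs=(("constant", 0.4), ("constant", -0.3)),
        tie_rounding=1,
        t_horizon=3.0,
        seed=7,
    )
    data, _ = tv.simulate_dataset(spec)
    return data


@pytest.fixture(scope="session")
def strat_data():
    """n=150 over 2 strata with different baseline levels."""
    spec = tv.SimulationSpec(
        n=150,
        p=2,
        beta_funcs=(("constant", 0.5), ("linear", 0.0, 0.3)),
        n_strata=2,
        stratum_multipliers=(1.0, 2.5),
        t_horizon=3.0,
        seed=21,
    )
    data, _ = tv.simulate_dataset(spec)
    return data


@pytest.fixture(scope="session")
def basis_k4(small_data):
    return tv.make_basis(
        np.unique(small_data.time[small_data.event == 1]), K=4, degree=3
    )
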