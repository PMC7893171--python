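import numpy as np
import pytest

from dimerscope.synthetic import (
    SyntheticSystemSpec,
    generate_membrane_system,
    generate_palm_bridge_pair,
)
from dimerscope.synthetic.membrane import make_c2_dimer_frames
from dimerscope.synthetic.umbrella import (
    AnalyticPMFSpec,
    default_restraints,
    generate_umbrella_windows,
)


@pytest.fixture(scope="session")
def small_membrane():
    """Two proteins with a designed TM9/TM9 interface; binds quickly."""
    spec = SyntheticSystemSpec(
        n_proteins=2, box=(10.5, 10.5, 10.0), n_frames=200, dt_frame=10.0,
        seed=3,
    )
    topology, frames, truth = generate_membrane_system(spec)
    return spec, topology, frames, truth


@pytest.fixture(scope="session")
def palm_bridge():
    topology, frames, truth = generate_palm_bridge_pair(n_frames=150, seed=5)
    return topology, frames, truth


@pytest.fixture(scope="session")
def c2_dimer():
    topology, frames = make_c2_dimer_frames(spin=0.7, n_frames=1)
    return topology, frames


@pytest.fixture(scope="session")
def double_well_windows():
    """Modest-size umbrella dataset from the default double-well PMF."""
    pmf = AnalyticPMFSpec.double_well()
    windows, truth = generate_umbrella_windows(
        pmf, default_restraints(), n_samples_per_window=1500, seed=11,
    )
    return pmf, windows, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
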