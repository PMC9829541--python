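import numpy as np
import pytest

from hypergeo import geomfit, synth

RMAX_GRID = np.arange(5.0, 16.01, 1.0)


@pytest.fixture(scope="session")
def demo_session():
    """Small synthetic square-box session shared by read-only tests."""
    traj = synth.simulate_trajectory(180.0, 600.0, seed=101)
    pop = synth.generate_population(40, seed=102)
    spikes = synth.simulate_spikes(pop, traj, seed=103)
    return traj, pop, spikes


@pytest.fixture(scope="session")
def library_n50():
    """Shared 3-D hyperbolic ensemble library (50 points, 50 reps).

    Ensembles are independent of the experimental matrices they are
    compared against, so the radius-recovery and discrimination tests
    can share one library.
    """
    lib = geomfit.EnsembleLibrary(n_points=50, n_reps=50, dim=3, eps=0.05,
                                  seed=42, max_dim=2)
    for r in RMAX_GRID:
        lib.get(r)
    return lib


@pytest.fixture(scope="session")
def library_n40():
    """Shared ensemble library for the spike-train shuffle control."""
    lib = geomfit.EnsembleLibrary(n_points=40, n_reps=30, dim=3, eps=0.05,
                                  seed=11, max_dim=2)
    for r in RMAX_GRID:
        lib.get(r)
    return lib
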