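import numpy as np
import pytest

from spatialews.grid import SpatialGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20140321)


@pytest.fixture
def white_noise_grid(rng):
    """64x64 iid standard-normal field (structureless reference)."""
    return SpatialGrid(rng.standard_normal((64, 64)), value_kind="continuous")


@pytest.fixture
def checkerboard():
    n = 16
    vals = np.indices((n, n)).sum(axis=0) % 2
    return SpatialGrid(vals.astype(float), value_kind="discrete_occupancy")


@pytest.fixture(scope="session")
def ca_sequence():
    """Facilitation-CA gradient shared across tests (moderate size)."""
    from spatialews.simulators import simulate_facilitation_ca

    return simulate_facilitation_ca(grid_size=100, seed=7, burn_in=300, relax=150)


@pytest.fixture(scope="session")
def turing_snapshot():
    """One mid-gradient patterned snapshot of the three-PDE model."""
    from spatialews.simulators import simulate_turing_pde

    seq = simulate_turing_pde(
        grid_size=64, driver_values=(1.05, 1.0, 0.96, 0.92), seed=3,
        burn_in=300.0, relax=80.0,
    )
    return seq.snapshots[-1]


@pytest.fixture(scope="session")
def turing_spots_snapshot():
    """A spots-regime snapshot large enough to carry many patches."""
    from spatialews.simulators import simulate_turing_pde

    seq = simulate_turing_pde(
        grid_size=100, driver_values=(1.0, 0.92, 0.86), seed=3,
        burn_in=300.0, relax=100.0,
    )
    return seq.snapshots[-1]
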