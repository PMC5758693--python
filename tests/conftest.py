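"""Shared fixtures.

The closed-loop fixtures are session-scoped because each forward solve
factorizes an ~80k-DOF complex system (about two minutes); every test that
needs a simulated field shares the same solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from mresim.forward import HarmonicField
from mresim.phantom import VoxelGrid
from mresim.pipeline import default_config, run_experiment
from mresim.rheology import ZenerParams

GEL = ZenerParams(mu0=7500.0, mu1=7500.0, tau1=0.025, nu=0.499, rho=1000.0)
STIFF = ZenerParams(mu0=15000.0, mu1=15000.0, tau1=0.025, nu=0.499, rho=1000.0)


@pytest.fixture(scope="session")
def gel() -> ZenerParams:
    return GEL


@pytest.fixture(scope="session")
def stiff() -> ZenerParams:
    return STIFF


def plane_shear_wave(
    k: complex,
    spacing: float,
    shape=(36, 12, 12),
    frequency: float = 250.0,
    direction: np.ndarray | None = None,
) -> HarmonicField:
    """Transverse plane wave u = e_pol * exp(i k x.n) sampled on grid nodes.

    Default: propagation along x, polarization along y.  ``direction`` (unit
    3-vector) tilts the propagation; polarization is chosen orthogonal.
    """
    grid = VoxelGrid(shape, spacing)
    coords = np.meshgrid(*(grid.node_coords(a) for a in range(3)), indexing="ij")
    if direction is None:
        phase = coords[0]
        pol = np.array([0.0, 1.0, 0.0])
    else:
        n = np.asarray(direction, float)
        n = n / np.linalg.norm(n)
        phase = n[0] * coords[0] + n[1] * coords[1] + n[2] * coords[2]
        trial = np.array([0.0, 1.0, 0.0])
        if abs(n @ trial) > 0.9:
            trial = np.array([1.0, 0.0, 0.0])
        pol = trial - (trial @ n) * n
        pol /= np.linalg.norm(pol)
    u = np.exp(1j * k * phase)[..., None] * pol
    return HarmonicField(grid=grid, values=u.astype(np.complex128), frequency=frequency)


@pytest.fixture(scope="session")
def closed_loop_report():
    """Scaled-down homogeneous closed loop at 62.5, 125 and 250 Hz."""
    return run_experiment(default_config(seed=1))


@pytest.fixture(scope="session")
def hetero_report():
    """Scaled-down heterogeneous closed loop: 20 mm twice-as-stiff cylinder
    in the reference gel block, 250 Hz."""
    from mresim.pipeline import RunConfig

    payload = default_config(seed=1).model_dump()
    payload["excitation"]["frequencies_hz"] = [250.0]
    payload["inclusion"] = {"material": "stiff", "diameter_mm": 20.0}
    return run_experiment(RunConfig.model_validate(payload))


@pytest.fixture()
def tiny_config():
    """A seconds-scale configuration for determinism and CLI tests."""
    cfg = default_config(seed=3).model_copy(deep=True)
    cfg.phantom.size_mm = (30.0, 20.0, 15.0)
    cfg.phantom.spacing_mm = 2.5
    cfg.excitation.frequencies_hz = [125.0]
    cfg.solver.min_elements_per_wavelength = 8.0
    return cfg
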