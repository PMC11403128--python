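import numpy as np
import pytest

from emgvestal.forward import reduce_orientations, sphere_leadfield
from emgvestal.geometry import SourceGrid, build_source_grid, spherical_cap_sensors
from emgvestal.projection import SpatialModes


@pytest.fixture(scope="session")
def desk_geometry():
    """Desk-scale geometry shared across tests: ~700-node shell grid, 102
    magnetometers, sphere lead field."""
    from emgvestal.simulate import default_geometry

    grid, sensors = default_geometry()
    lf = reduce_orientations(sphere_leadfield(grid, sensors), grid, sensors)
    return grid, sensors, lf


@pytest.fixture(scope="session")
def toy_geometry():
    """Small geometry for solver-level tests: ~56 nodes, 40 sensors."""
    def inside(xyz):
        r = np.linalg.norm(xyz, axis=1)
        return (r > 0.015) & (r < 0.045)

    grid = build_source_grid(("mask", inside, (-0.045 * np.ones(3), 0.045 * np.ones(3))), 0.02)
    sensors = spherical_cap_sensors(40, 0.102)
    lf = reduce_orientations(sphere_leadfield(grid, sensors), grid, sensors)
    return grid, sensors, lf


@pytest.fixture(scope="session")
def two_depth_geometry():
    """Two concentric shells of nodes (22 mm and 48 mm) under a sparse sensor
    array, so the gain is rank-deficient and depth leverage varies."""
    ths = np.deg2rad([15, 30, 45, 60])
    phs = np.deg2rad([0, 90, 180, 270])
    dirs = np.array(
        [[np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)] for t in ths for p in phs]
    )
    coords = np.vstack([0.022 * dirs, 0.048 * dirs])
    grid = SourceGrid(node_coords=coords, spacing=0.01, region="two-depth fixture")
    sensors = spherical_cap_sensors(24, 0.102)
    lf = reduce_orientations(sphere_leadfield(grid, sensors), grid, sensors)
    return grid, sensors, lf


def modes_from_columns(B: np.ndarray) -> SpatialModes:
    """SpatialModes wrapping the SVD of explicit sensor-pattern columns."""
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    return SpatialModes(U=U, S=s, V=Vt.T, k=B.shape[1],
                        delays_ms=np.arange(B.shape[1], dtype=float))
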