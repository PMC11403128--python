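"""Sensor arrays and volumetric source grids.

All geometry is SI (meters) in a head-centered frame whose origin is the
center of the conducting sphere used by the analytic forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorArray", "SourceGrid", "build_source_grid", "spherical_cap_sensors"]


@dataclass
class SensorArray:
    """Point-magnetometer array: coil positions and unit coil normals.

    ``sphere_center`` is the origin of the single-sphere conductor model used
    both for the forward solution and the "sensors outside / sources inside"
    sanity checks.
    """

    positions: np.ndarray  # (M, 3) meters
    orientations: np.ndarray  # (M, 3) unit normals
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.sphere_center = np.asarray(self.sphere_center, dtype=float).reshape(3)
        if self.positions.shape != self.orientations.shape or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions {self.positions.shape} and orientations "
                f"{self.orientations.shape} must both be (M, 3)"
            )
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit vectors (|1 - norm| <= 1e-9)")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class SourceGrid:
    """Cubic lattice of candidate dipole locations clipped to a region."""

    node_coords: np.ndarray  # (P, 3) meters
    spacing: float
    region: str = ""  # provenance, e.g. "sphere(c=[0 0 0], r=0.05)"
    excluded_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.node_coords = np.atleast_2d(np.asarray(self.node_coords, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def nearest_node(self, coord) -> int:
        """Index of the grid node closest to ``coord`` (meters)."""
        d = np.linalg.norm(self.node_coords - np.asarray(coord, float), axis=1)
        return int(np.argmin(d))

    def to_csv(self, path) -> None:
        """Node index + coordinates in millimeters, 3 decimals."""
        import pandas as pd

        mm = np.round(self.node_coords * 1000.0, 3)
        pd.DataFrame(
            {"node": np.arange(self.n_nodes), "x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2]}
        ).to_csv(path, index=False)


def build_source_grid(region, spacing: float = 0.005) -> SourceGrid:
    """Build a cubic source lattice clipped to a region.

    Parameters
    ----------
    region
        Either ``("sphere", center, radius)`` (meters) or a boolean mask
        callable ``f(coords) -> bool array`` paired with a bounding box as
        ``("mask", f, (lo, hi))``.
    spacing
        Lattice constant in meters (default 0.005, i.e. 5 mm).

    Node order is deterministic: lexicographic in (z, y, x).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if region[0] == "sphere":
        _, center, radius = region
        center = np.asarray(center, dtype=float).reshape(3)
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        lo, hi = center - radius, center + radius
        inside = lambda xyz: np.linalg.norm(xyz - center, axis=1) < radius
        label = f"sphere(c={np.array2string(center)}, r={radius:g})"
    elif region[0] == "mask":
        _, fn, (lo, hi) = region
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        inside = fn
        label = "mask"
    else:
        raise ValueError(f"unknown region kind {region[0]!r}")

    axes = [np.arange(np.ceil(lo[i] / spacing), np.floor(hi[i] / spacing) + 1) * spacing for i in range(3)]
    if any(a.size == 0 for a in axes):
        raise ValueError(f"empty grid: region {label} admits no lattice point at spacing {spacing}")
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])  # z slowest, then y, then x
    keep = inside(pts)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError(f"empty grid: region {label} admits no lattice point at spacing {spacing}")
    return SourceGrid(node_coords=pts, spacing=float(spacing), region=label)


def spherical_cap_sensors(
    n_sensors: int = 102,
    radius: float = 0.102,
    max_polar_deg: float = 110.0,
    center=(0.0, 0.0, 0.0),
) -> SensorArray:
    """Generic helmet stand-in: point magnetometers on a spherical cap.

    Sensors are laid out on a Fibonacci spiral over the cap (polar angle from
    +z up to ``max_polar_deg``), with radial coil normals — the idealized
    arrangement for a sphere conductor, for which radial magnetometers carry
    all the tangential-dipole signal.
    """
    center = np.asarray(center, dtype=float)
    i = np.arange(n_sensors)
    golden = (1.0 + 5**0.5) / 2.0
    cos_max = np.cos(np.deg2rad(max_polar_deg))
    # uniform in cos(theta) over [cos_max, 1]
    costh = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_sensors
    theta = np.arccos(costh)
    phi = 2.0 * np.pi * i / golden
    unit = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return SensorArray(positions=center + radius * unit, orientations=unit, sphere_center=center)
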