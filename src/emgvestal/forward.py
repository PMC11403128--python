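"""Forward modeling: sphere lead fields, orientation reduction, gain SVD, depth weights.

The measurement model is ``B = G Q + N`` with ``G`` the M×2P gain matrix: two
tangential dipole orientations per grid node (a dipole oriented along the
radius of a spherically symmetric conductor is magnetically silent, so only
two orientations per node carry signal). For imported lead fields computed
with a realistic head model, the two retained orientations are the dominant
pair from the per-node SVD of the M×3 lead field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import SensorArray, SourceGrid

__all__ = [
    "LeadField",
    "GainSVD",
    "DepthWeights",
    "sphere_leadfield",
    "reduce_orientations",
    "compute_gain_svd",
    "depth_weights",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class LeadField:
    """M×2P gain matrix with the per-node tangential orientation pair."""

    G: np.ndarray  # (M, 2P), tesla per A·m
    orientation_pairs: np.ndarray  # (P, 2, 3) unit vectors (theta_hat, phi_hat)
    grid: SourceGrid | None = None
    sensors: SensorArray | None = None
    lead3: np.ndarray | None = None  # (P, M, 3) full per-node lead field, if available
    excluded_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.G.shape[1] // 2


@dataclass
class GainSVD:
    """Truncated SVD of the gain matrix, G ≈ U_G diag(S_G) V_Gᵀ."""

    U: np.ndarray  # (M, r)
    S: np.ndarray  # (r,) descending, strictly positive
    V: np.ndarray  # (2P, r)
    truncation: dict

    @property
    def rank(self) -> int:
        return self.S.size


@dataclass
class DepthWeights:
    """Per-node weights counteracting the superficial bias of minimum-norm fits.

    ``w_raw[j] = ||row j of V_G||²`` (the leverage of source component j on the
    retained gain subspace, ``diag(V_G V_Gᵀ)``); ``omega`` combines each node's
    two orientation leverages into one positive scalar for the group norm.
    """

    w_raw: np.ndarray  # (2P,)
    omega: np.ndarray  # (P,)
    combine: str = "sum"


def _sarvas_fields(node: np.ndarray, sensors: SensorArray) -> np.ndarray:
    """M×3 lead field of a dipole at ``node`` in a homogeneous sphere.

    Column c is the sensor-projected field of a unit dipole moment along axis
    c. Closed form for the field outside a spherically symmetric conductor
    centered at ``sensors.sphere_center``.
    """
    r = sensors.positions - sensors.sphere_center  # (M, 3)
    r0 = node - sensors.sphere_center  # (3,)
    a_vec = r - r0  # (M, 3)
    a = np.linalg.norm(a_vec, axis=1)  # (M,)
    R = np.linalg.norm(r, axis=1)  # (M,)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (R * a + R**2 - r0 @ r.T)  # (M,)
    gradF = (
        (a**2 / R + adotr / a + 2.0 * a + 2.0 * R)[:, None] * r
        - (a + 2.0 * R + adotr / a)[:, None] * r0[None, :]
    )  # (M, 3)
    # q x r0 for unit moments e_x, e_y, e_z: rows of the cross-product matrix
    ex_r0 = np.cross(np.eye(3), r0)  # (3, 3); row c = e_c x r0
    lead = np.empty((sensors.n_sensors, 3))
    for c in range(3):
        # B = mu0/(4 pi F^2) * (F*(q x r0) - ((q x r0).r) gradF)
        Bfull = MU0_OVER_4PI / (F**2)[:, None] * (
            F[:, None] * ex_r0[c][None, :] - (r @ ex_r0[c])[:, None] * gradF
        )
        lead[:, c] = np.einsum("ij,ij->i", Bfull, sensors.orientations)
    return lead


def sphere_leadfield(grid: SourceGrid, sensors: SensorArray) -> np.ndarray:
    """Full per-node M×3 lead fields for every grid node (Sarvas sphere model).

    Returns an array of shape (P, M, 3). Use :func:`reduce_orientations` to
    obtain the M×2P gain matrix.
    """
    r0_all = grid.node_coords - sensors.sphere_center
    node_r = np.linalg.norm(r0_all, axis=1)
    sensor_r = np.linalg.norm(sensors.positions - sensors.sphere_center, axis=1)
    if np.any(node_r < 1e-9):
        raise ValueError("source node at sphere center: tangential frame undefined")
    if np.any(sensor_r <= node_r.max()):
        raise ValueError(
            f"sensors must lie outside all source nodes "
            f"(min sensor radius {sensor_r.min():.4f} m <= max node radius {node_r.max():.4f} m)"
        )
    out = np.empty((grid.n_nodes, sensors.n_sensors, 3))
    for p in range(grid.n_nodes):
        out[p] = _sarvas_fields(grid.node_coords[p], sensors)
    return out


def _fix_sign(v: np.ndarray) -> float:
    """Deterministic sign: make the first component with |x| > tol positive."""
    nz = np.flatnonzero(np.abs(v) > 1e-12 * max(np.abs(v).max(), 1e-300))
    if nz.size == 0:
        return 1.0
    return 1.0 if v[nz[0]] > 0 else -1.0


def reduce_orientations(
    lead3: np.ndarray, grid: SourceGrid | None = None, sensors: SensorArray | None = None
) -> LeadField:
    """Keep the two dominant orientations per node from the M×3 lead-field SVD.

    Per node, the right singular vectors of the M×3 lead field give an
    orthonormal orientation triplet ordered by sensor-space energy; the first
    two (tangential, for a sphere conductor) are kept as theta_hat/phi_hat and
    the gain columns are the lead fields along them. Nodes with an all-zero
    lead field are flagged and excluded from the solve.
    """
    lead3 = np.asarray(lead3, dtype=float)
    if not np.all(np.isfinite(lead3)):
        raise ValueError("lead field contains non-finite values")
    P, M, _ = lead3.shape
    G = np.zeros((M, 2 * P))
    pairs = np.zeros((P, 2, 3))
    excluded = []
    for p in range(P):
        A = lead3[p]
        scale = np.abs(A).max()
        if scale == 0.0:
            excluded.append(p)
            pairs[p] = np.array([[1.0, 0, 0], [0, 1.0, 0]])
            continue
        _, s, Vt = np.linalg.svd(A, full_matrices=False)
        if s[0] <= 1e-12 * scale:
            excluded.append(p)
            pairs[p] = np.array([[1.0, 0, 0], [0, 1.0, 0]])
            continue
        for k in range(2):
            v = Vt[k] * _fix_sign(Vt[k])
            pairs[p, k] = v
            G[:, 2 * p + k] = A @ v
    lf = LeadField(
        G=G,
        orientation_pairs=pairs,
        grid=grid,
        sensors=sensors,
        lead3=lead3,
        excluded_nodes=np.asarray(excluded, dtype=int),
    )
    if excluded and grid is not None:
        grid.excluded_nodes = lf.excluded_nodes
    if excluded:
        warnings.warn(f"{len(excluded)} rank-0 node(s) excluded from the solve")
    return lf


def compute_gain_svd(G: np.ndarray, truncation: dict | None = None) -> GainSVD:
    """Truncated SVD of the gain matrix.

    ``truncation`` is one of ``{"rel_threshold": x}`` (keep s_i/s_1 > x;
    default x = 1e-6), ``{"energy": f}`` (smallest rank capturing fraction f of
    squared singular values), or ``{"rank": r}``.
    """
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("gain matrix contains non-finite values")
    if truncation is None:
        truncation = {"rel_threshold": 1e-6}
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    if s[0] == 0.0:
        raise ValueError("gain matrix is identically zero")
    if "rel_threshold" in truncation:
        r = int(np.sum(s / s[0] > truncation["rel_threshold"]))
    elif "energy" in truncation:
        cum = np.cumsum(s**2) / np.sum(s**2)
        r = int(np.searchsorted(cum, truncation["energy"]) + 1)
    elif "rank" in truncation:
        r = int(min(truncation["rank"], s.size))
    else:
        raise ValueError(f"unknown truncation rule {truncation}")
    r = max(r, 1)
    U, s, Vt = U[:, :r].copy(), s[:r].copy(), Vt[:r].copy()
    # deterministic sign: largest-|.| component of each U column positive
    for i in range(r):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    return GainSVD(U=U, S=s, V=Vt.T.copy(), truncation=dict(truncation))


def depth_weights(gsvd: GainSVD, combine: str = "sum") -> DepthWeights:
    """Depth-bias weights from the retained gain subspace.

    ``w_raw = diag(V_G V_Gᵀ)`` — the leverage each source component exerts on
    the retained sensor subspace; superficial nodes have larger leverage, so
    weighting the group norm by it penalizes them and removes the superficial
    bias. ``omega_j = sqrt(w_{2j-1} + w_{2j})`` by default (``combine="max"``
    uses the larger of the pair instead of the sum).
    """
    w_raw = np.einsum("ij,ij->i", gsvd.V, gsvd.V)  # row squared norms
    pairs = w_raw.reshape(-1, 2)
    if combine == "sum":
        per_node = pairs.sum(axis=1)
    elif combine == "max":
        per_node = pairs.max(axis=1)
    else:
        raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")
    omega = np.sqrt(per_node)
    # nodes with no lead-field support get the maximum weight so the solver
    # never places current there
    dead = per_node <= 1e-12 * max(per_node.max(), 1e-300)
    if np.any(dead):
        omega = omega.copy()
        omega[dead] = omega.max() if omega.max() > 0 else 1.0
    return DepthWeights(w_raw=w_raw, omega=omega, combine=combine)
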