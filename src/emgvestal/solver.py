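"""Depth-weighted, rotation-invariant group-sparse minimum-L1 inverse solver.

For each dominant spatial mode i of the EMG-projected data the source map
h_i (2P×1) must reproduce the mode pattern through the gain matrix. With the
truncated gain SVD G = U_G S_G V_Gᵀ the per-mode linear system reads

    S_G V_Gᵀ h_i = U_Gᵀ u_i s_i ,            i = 1 … k

(the consistent substitution of the gain SVD into the projected-data system).
The under-determined system is resolved by the group-sparse minimum-L1
objective, generalized across orientations and modes:

    minimize  Σ_j  ω_j sqrt( Σ_i  h_ijθ² + h_ijφ² )

with ω the depth weights from diag(V_G V_Gᵀ). Grouping the two tangential
orientations per node makes the solution invariant to rotations of the dipole
in its tangent plane; grouping across modes makes all mode maps share one
sparse support. The equality constraints are relaxed to second-order cones
‖A h_i − b_i‖ ≤ δ‖b_i‖ (δ = 1e-3 by default; δ = 0 requests exact equality),
and the program is solved by ADMM: alternating exact projection onto the cone
intersection (a secular-equation solve in the r-dimensional gain basis) and a
group soft-threshold. The iteration is deterministic — no randomized
initialization — so repeated solves are bit-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import DepthWeights, GainSVD
from .projection import SpatialModes

__all__ = [
    "InverseProblem",
    "SourceDelayMap",
    "SourceImage",
    "assemble_constraints",
    "solve_gsocp",
    "source_magnitude",
    "delay_resolved_image",
    "combine_channels",
]


@dataclass
class InverseProblem:
    gsvd: GainSVD
    modes: SpatialModes
    weights: DepthWeights
    delta: float = 1e-3  # cone radius as a fraction of ‖rhs_i‖
    epsilon: np.ndarray | None = None  # absolute per-mode cone radii (overrides delta)
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_iter: int = 200_000
    rho: float = 1.0
    on_max_iter: str = "warn"  # "warn" | "raise"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.modes.k >= 1 and self.gsvd.U.shape[0] != self.modes.U.shape[0]:
            raise ValueError(
                f"gain and modes disagree on sensor count: "
                f"{self.gsvd.U.shape[0]} vs {self.modes.U.shape[0]}"
            )


@dataclass
class SourceDelayMap:
    """Per-mode source maps H (2P×k) and solver diagnostics."""

    H: np.ndarray
    status: str
    objective: float
    residuals: np.ndarray  # per-mode ‖A h_i − b_i‖
    rhs_norms: np.ndarray
    n_iter: int = 0
    delta: float = 0.0
    delays_ms: np.ndarray = field(default_factory=lambda: np.zeros(0))
    modes_V: np.ndarray | None = None  # (D, k) retained right singular vectors


@dataclass
class SourceImage:
    """Per-node nonnegative magnitude map."""

    A: np.ndarray  # (P,)
    map_kind: str  # "mode_magnitude" | "max_over_delays"
    band: str = ""
    emg_channels: list = field(default_factory=list)
    threshold: float | None = None
    saturation: float | None = None
    winning_delay_ms: np.ndarray | None = None  # (P,), NaN where undefined
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.A.size

    def sparsity_fraction(self, rel: float = 1e-6) -> float:
        """Fraction of nodes whose magnitude exceeds ``rel``×max(A)."""
        m = self.A.max()
        if m == 0.0:
            return 0.0
        return float(np.mean(self.A > rel * m))


def assemble_constraints(gsvd: GainSVD, modes: SpatialModes, i: int):
    """Constraint system (A_mat, rhs) for spatial mode ``i`` (0-based).

    A_mat = S_G V_Gᵀ (r×2P); rhs = U_Gᵀ u_i s_i. Any h with G h = u_i s_i
    satisfies A_mat h = rhs exactly.
    """
    if not (0 <= i < modes.k):
        raise ValueError(f"mode index {i} outside 0..{modes.k - 1}")
    A_mat = gsvd.S[:, None] * gsvd.V.T
    rhs = gsvd.U.T @ (modes.U[:, i] * modes.S[i])
    return A_mat, rhs


def _project_cone(v_cols, V, S, b, eps, mu_warm):
    """Project each column of ``v_cols`` (2P×k) onto {h: ‖S V.T h − b_i‖ ≤ eps_i}.

    The constraint only sees c = Vᵀh, so the projection keeps the V-orthogonal
    part and moves c onto the ellipsoidal ball by solving the 1-D secular
    equation  Σ_l r0_l²/(1+μS_l²)² = eps² for the multiplier μ ≥ 0.
    """
    C0 = V.T @ v_cols  # (r, k)
    Cnew = C0.copy()
    S2 = S * S
    for i in range(v_cols.shape[1]):
        c0 = C0[:, i]
        r0 = S * c0 - b[:, i]
        if eps[i] == 0.0:
            Cnew[:, i] = b[:, i] / S
            continue
        nr0sq = float(r0 @ r0)
        if nr0sq <= eps[i] ** 2:
            mu_warm[i] = 0.0
            continue
        mu = max(mu_warm[i], 0.0)
        target = eps[i] ** 2
        for _ in range(100):
            den = 1.0 + mu * S2
            g = float(np.sum(r0 * r0 / (den * den))) - target
            if abs(g) <= 1e-14 * target + 1e-300:
                break
            gp = float(np.sum(-2.0 * S2 * r0 * r0 / (den * den * den)))
            mu_new = mu - g / gp
            if not np.isfinite(mu_new) or mu_new < 0:
                mu_new = 2.0 * mu + 1.0 if g > 0 else mu / 2.0
            mu = mu_new
        mu_warm[i] = mu
        Cnew[:, i] = (c0 + mu * S * b[:, i]) / (1.0 + mu * S2)
    return v_cols + V @ (Cnew - C0)


def solve_gsocp(problem: InverseProblem) -> SourceDelayMap:
    """Solve the generalized second-order cone program for the source maps.

    Returns the 2P×k source delay-map matrix H across the k dominant modes.
    The returned iterate is always feasible (it is the exact projection onto
    the constraint set); on hitting ``max_iter`` without meeting the ADMM
    tolerances the result is returned with status "max_iter" (a warning, or an
    error when ``on_max_iter="raise"``).
    """
    gsvd, modes, k = problem.gsvd, problem.modes, problem.modes.k
    if k < 1:
        return SourceDelayMap(
            H=np.zeros((gsvd.V.shape[0], 0)), status="skipped (k=0)", objective=0.0,
            residuals=np.zeros(0), rhs_norms=np.zeros(0), delta=problem.delta,
            delays_ms=modes.delays_ms, modes_V=np.zeros((modes.V.shape[0], 0)),
        )
    V, S = gsvd.V, gsvd.S
    twoP, r = V.shape
    P = twoP // 2
    omega = np.asarray(problem.weights.omega, dtype=float)
    if omega.size != P or np.any(omega <= 0):
        raise ValueError("weights.omega must be strictly positive with one entry per node")

    b = np.column_stack([assemble_constraints(gsvd, modes, i)[1] for i in range(k)])
    rhs_norms = np.linalg.norm(b, axis=0)

    # scale to unit-ish magnitudes: h = (bscale/gscale) h~, b~ = b/bscale, S~ = S/gscale
    gscale = float(S[0])
    bscale = float(rhs_norms.max()) if rhs_norms.max() > 0 else 1.0
    Sn = S / gscale
    bn = b / bscale
    if problem.epsilon is not None:
        eps = np.broadcast_to(np.asarray(problem.epsilon, float), (k,)) / bscale
        # a cone that already contains the origin pins the trivial solution
        eps = np.minimum(eps, np.linalg.norm(bn, axis=0))
    else:
        eps = problem.delta * np.linalg.norm(bn, axis=0)

    rho = problem.rho
    Z = np.zeros((twoP, k))
    Uu = np.zeros((twoP, k))
    mu_warm = np.zeros(k)
    H = _project_cone(Z - Uu, V, Sn, bn, eps, mu_warm)
    n = np.sqrt(twoP * k)
    status = "max_iter"
    it = 0
    for it in range(1, problem.max_iter + 1):
        H = _project_cone(Z - Uu, V, Sn, bn, eps, mu_warm)
        T = H + Uu
        gn = np.sqrt(np.einsum("ijk->ik", (T.reshape(P, 2, k) ** 2)).sum(axis=1))  # (P,)
        shrink = np.maximum(0.0, 1.0 - (omega / rho) / np.maximum(gn, 1e-300))
        Z_old = Z
        Z = (T.reshape(P, 2, k) * shrink[:, None, None]).reshape(twoP, k)
        Uu = Uu + H - Z
        r_norm = np.linalg.norm(H - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps_pri = n * problem.abs_tol + problem.rel_tol * max(
            np.linalg.norm(H), np.linalg.norm(Z)
        )
        eps_dual = n * problem.abs_tol + problem.rel_tol * rho * np.linalg.norm(Uu)
        if r_norm <= eps_pri and s_norm <= eps_dual:
            status = "optimal"
            break
        if it % 10 == 0:
            if r_norm > 10.0 * s_norm:
                rho *= 2.0
                Uu /= 2.0
            elif s_norm > 10.0 * r_norm:
                rho /= 2.0
                Uu *= 2.0

    H = _project_cone(Z - Uu, V, Sn, bn, eps, mu_warm)  # final feasible iterate
    H_out = H * (bscale / gscale)
    obj = float(
        np.sum(omega * np.sqrt((H_out.reshape(P, 2, k) ** 2).sum(axis=(1, 2))))
    )
    resid = np.linalg.norm((Sn[:, None] * (V.T @ H) - bn), axis=0) * bscale
    if status == "max_iter":
        msg = f"GSOCP did not meet tolerance in {problem.max_iter} iterations"
        if problem.on_max_iter == "raise":
            raise RuntimeError(msg + " (status: max_iter)")
        warnings.warn(msg)
    return SourceDelayMap(
        H=H_out, status=status, objective=obj, residuals=resid, rhs_norms=rhs_norms,
        n_iter=it, delta=problem.delta, delays_ms=modes.delays_ms,
        modes_V=modes.V[:, :k].copy(),
    )


def source_magnitude(H: SourceDelayMap, band: str = "", emg_channel: int | None = None) -> SourceImage:
    """Voxel-wise magnitude image A: per node, the root-sum-square of the
    node's two orientation rows across all modes (the per-node aggregation of
    diag(H Hᵀ))."""
    twoP, k = H.H.shape
    A = np.sqrt((H.H.reshape(twoP // 2, 2, max(k, 1)) ** 2).sum(axis=(1, 2))) if k else np.zeros(twoP // 2)
    return SourceImage(
        A=A, map_kind="mode_magnitude", band=band,
        emg_channels=[] if emg_channel is None else [emg_channel],
    )


def delay_resolved_image(
    H: SourceDelayMap,
    modes: SpatialModes | None = None,
    band: str = "",
    emg_channel: int | None = None,
    return_cube: bool = False,
):
    """Delay-domain maps and the max-across-delays image.

    Back-projects the mode maps onto the delay axis, Q_d = H V_Fᵀ (restricted
    to the k retained modes), combines each node's two orientations as
    sqrt(qθ² + qφ²) per delay, and takes the maximum across delays per node.
    The winning delay is recorded per node (NaN where the map is zero).
    """
    Vf = H.modes_V if modes is None else modes.V[:, : H.H.shape[1]]
    delays = H.delays_ms if modes is None else modes.delays_ms
    twoP, k = H.H.shape
    P = twoP // 2
    if k == 0 or Vf is None or Vf.shape[1] == 0:
        img = SourceImage(
            A=np.zeros(P), map_kind="max_over_delays", band=band,
            emg_channels=[] if emg_channel is None else [emg_channel],
            winning_delay_ms=np.full(P, np.nan), meta={"all_zero": True},
        )
        return (img, np.zeros((P, 0))) if return_cube else img
    Qd = H.H @ Vf.T  # (2P, D)
    amp = np.sqrt((Qd.reshape(P, 2, -1) ** 2).sum(axis=1))  # (P, D)
    A = amp.max(axis=1)
    win = np.asarray(delays, dtype=float)[np.argmax(amp, axis=1)]
    win = np.where(A > 0, win, np.nan)
    img = SourceImage(
        A=A, map_kind="max_over_delays", band=band,
        emg_channels=[] if emg_channel is None else [emg_channel],
        winning_delay_ms=win, meta={"all_zero": bool(np.all(A == 0))},
    )
    return (img, amp) if return_cube else img


def combine_channels(images: list[SourceImage]) -> SourceImage:
    """Euclidean-norm combination of per-EMG-channel magnitude maps."""
    if not images:
        raise ValueError("no images to combine")
    first = images[0]
    for img in images[1:]:
        if img.A.size != first.A.size:
            raise ValueError(
                f"mismatched grids: {img.A.size} vs {first.A.size} nodes"
            )
        if img.map_kind != first.map_kind:
            raise ValueError(
                f"mismatched map kinds: {img.map_kind} vs {first.map_kind}"
            )
        if img.band != first.band:
            raise ValueError(f"mismatched bands: {img.band} vs {first.band}")
    stack = np.stack([img.A for img in images])
    A = np.sqrt((stack**2).sum(axis=0))
    win = None
    if all(img.winning_delay_ms is not None for img in images):
        dominant = np.argmax(stack, axis=0)
        wins = np.stack([img.winning_delay_ms for img in images])
        win = wins[dominant, np.arange(A.size)]
    channels = sorted({c for img in images for c in img.emg_channels})
    return SourceImage(
        A=A, map_kind=first.map_kind, band=first.band, emg_channels=channels,
        winning_delay_ms=win, meta={"combined": len(images)},
    )
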