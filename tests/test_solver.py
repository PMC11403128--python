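import numpy as np
import pytest

from emgvestal.forward import DepthWeights, compute_gain_svd, depth_weights
from emgvestal.solver import (
    InverseProblem,
    SourceDelayMap,
    assemble_constraints,
    combine_channels,
    delay_resolved_image,
    solve_gsocp,
    source_magnitude,
)

from conftest import modes_from_columns


def unit_weights(P):
    return DepthWeights(w_raw=np.ones(2 * P), omega=np.ones(P))


def one_hot_problem(G, node, psi=0.3, amp=1e-8, noise=None, weights=None, **kw):
    P = G.shape[1] // 2
    h = np.zeros(2 * P)
    h[2 * node] = np.cos(psi) * amp
    h[2 * node + 1] = np.sin(psi) * amp
    b = G @ h
    if noise is not None:
        b = b + noise
    gsvd = compute_gain_svd(G)
    wts = weights if weights is not None else depth_weights(gsvd)
    return InverseProblem(gsvd, modes_from_columns(b[:, None]), wts, **kw), h


class TestAssembleConstraints:
    def test_exact_solution_satisfies_constraints(self, toy_geometry):
        grid, _, lf = toy_geometry
        gsvd = compute_gain_svd(lf.G)
        rng = np.random.default_rng(0)
        h = np.zeros(2 * grid.n_nodes)
        h[10:14] = rng.standard_normal(4) * 1e-8
        b = lf.G @ h
        modes = modes_from_columns(b[:, None])
        A_mat, rhs = assemble_constraints(gsvd, modes, 0)
        assert np.linalg.norm(A_mat @ h - rhs) <= 1e-10 * np.linalg.norm(rhs)

    def test_rhs_is_subspace_projection_norm(self):
        rng = np.random.default_rng(1)
        G = rng.standard_normal((8, 30))
        gsvd = compute_gain_svd(G, {"rank": 5})
        y = rng.standard_normal(8)
        modes = modes_from_columns(y[:, None])
        _, rhs = assemble_constraints(gsvd, modes, 0)
        proj = gsvd.U @ (gsvd.U.T @ (modes.U[:, 0] * modes.S[0]))
        assert np.linalg.norm(rhs) == pytest.approx(np.linalg.norm(proj), rel=1e-10)

    def test_full_rank_equals_plain_system(self):
        rng = np.random.default_rng(2)
        G = rng.standard_normal((6, 6))
        gsvd = compute_gain_svd(G)
        y = rng.standard_normal(6)
        modes = modes_from_columns(y[:, None])
        A_mat, rhs = assemble_constraints(gsvd, modes, 0)
        h = np.linalg.solve(G, y)
        assert np.linalg.norm(A_mat @ h - rhs) <= 1e-10 * np.linalg.norm(rhs)

    def test_mode_index_bounds(self):
        rng = np.random.default_rng(3)
        G = rng.standard_normal((4, 8))
        modes = modes_from_columns(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            assemble_constraints(compute_gain_svd(G), modes, 2)


class TestSolveGSOCP:
    def test_zero_rhs_gives_exact_zero(self):
        rng = np.random.default_rng(4)
        G = rng.standard_normal((6, 10))
        prob = InverseProblem(
            compute_gain_svd(G), modes_from_columns(np.zeros((6, 1))), unit_weights(5)
        )
        sol = solve_gsocp(prob)
        assert np.all(sol.H == 0.0)

    def test_single_active_node_matches_dipole_scan(self):
        """On a well-separated noiseless toy the sparse solution concentrates
        on the node the exhaustive single-node least-squares scan selects."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            G = rng.standard_normal((6, 6))  # M=6, P=3, well-conditioned w.h.p.
            node = trial % 3
            prob, h_true = one_hot_problem(G, node, weights=unit_weights(3),
                                           delta=0.0, rel_tol=1e-10, abs_tol=1e-12)
            sol = solve_gsocp(prob)
            A = source_magnitude(sol).A
            b = G @ h_true
            scan = [
                np.linalg.norm(b - G[:, 2 * j : 2 * j + 2]
                               @ np.linalg.lstsq(G[:, 2 * j : 2 * j + 2], b, rcond=None)[0])
                for j in range(3)
            ]
            assert int(np.argmin(scan)) == node
            assert A[node] >= 0.99 * A.sum()

    def test_tangential_rotation_leaves_magnitudes_invariant(self, toy_geometry):
        grid, _, lf = toy_geometry
        node = grid.n_nodes // 2
        maps = []
        for psi in (0.2, 0.2 + np.pi / 4):
            prob, _ = one_hot_problem(lf.G, node, psi=psi, delta=0.0,
                                      rel_tol=1e-11, abs_tol=1e-13)
            maps.append(source_magnitude(solve_gsocp(prob)).A)
        rel = np.linalg.norm(maps[0] - maps[1]) / np.linalg.norm(maps[0])
        assert rel <= 1e-6

    def test_solution_is_sparse(self, desk_geometry):
        grid, _, lf = desk_geometry
        prob, _ = one_hot_problem(lf.G, grid.n_nodes // 3, delta=1e-3,
                                  rel_tol=1e-8, abs_tol=1e-11, max_iter=50_000)
        A = source_magnitude(solve_gsocp(prob)).A
        assert np.mean(A > 1e-3 * A.max()) <= 0.05

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(6)
        G = rng.standard_normal((6, 16))
        b = rng.standard_normal(6)
        mk = lambda: InverseProblem(
            compute_gain_svd(G), modes_from_columns(b[:, None]), unit_weights(8)
        )
        s1, s2 = solve_gsocp(mk()), solve_gsocp(mk())
        assert s1.objective == s2.objective
        assert np.array_equal(s1.H, s2.H)

    def test_residuals_within_cone(self):
        rng = np.random.default_rng(7)
        G = rng.standard_normal((6, 20))
        b = rng.standard_normal((6, 2))
        prob = InverseProblem(compute_gain_svd(G), modes_from_columns(b),
                              unit_weights(10), delta=0.05)
        sol = solve_gsocp(prob)
        assert np.all(sol.residuals <= 0.05 * sol.rhs_norms * (1 + 1e-6) + 1e-12)

    def test_k_zero_skips(self):
        rng = np.random.default_rng(8)
        G = rng.standard_normal((4, 8))
        modes = modes_from_columns(rng.standard_normal((4, 1)))
        modes.k = 0
        sol = solve_gsocp(InverseProblem(compute_gain_svd(G), modes, unit_weights(4)))
        assert sol.H.shape == (8, 0) and "skip" in sol.status


class TestSourceMagnitude:
    def test_one_hot_entry(self):
        H = SourceDelayMap(H=np.zeros((12, 1)), status="optimal", objective=0.0,
                           residuals=np.zeros(1), rhs_norms=np.zeros(1))
        H.H[2 * 5, 0] = 2.0  # node 5, theta orientation, mode 1
        A = source_magnitude(H).A
        assert A[5] == 2.0 and np.sum(A > 0) == 1

    def test_matches_dense_diag_aggregation(self):
        rng = np.random.default_rng(9)
        Hm = rng.standard_normal((10, 3))
        H = SourceDelayMap(H=Hm, status="optimal", objective=0.0,
                           residuals=np.zeros(3), rhs_norms=np.zeros(3))
        A = source_magnitude(H).A
        diag = np.diag(Hm @ Hm.T)  # 2P-long
        expected = np.sqrt(diag.reshape(-1, 2).sum(axis=1))
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_invariant_to_mode_rotation(self):
        rng = np.random.default_rng(10)
        Hm = rng.standard_normal((8, 2))
        Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        mk = lambda X: SourceDelayMap(H=X, status="optimal", objective=0.0,
                                      residuals=np.zeros(2), rhs_norms=np.zeros(2))
        np.testing.assert_allclose(source_magnitude(mk(Hm)).A,
                                   source_magnitude(mk(Hm @ Q)).A, atol=1e-12)


class TestDelayResolvedImage:
    def test_full_rank_forward_reprojection(self, toy_geometry):
        """With all modes retained the delay-domain source matrix reproduces
        the projected data through the gain matrix."""
        grid, _, lf = toy_geometry
        rng = np.random.default_rng(11)
        D = 6
        Qd_true = np.zeros((2 * grid.n_nodes, D))
        Qd_true[20:24] = rng.standard_normal((4, D)) * 1e-8
        F = lf.G @ Qd_true
        modes = modes_from_columns(F)
        gsvd = compute_gain_svd(lf.G)
        prob = InverseProblem(gsvd, modes, depth_weights(gsvd), delta=1e-6,
                              rel_tol=1e-9, abs_tol=1e-12)
        sol = solve_gsocp(prob)
        _, cube = delay_resolved_image(sol, modes, return_cube=True)
        Qd = sol.H @ modes.V[:, : modes.k].T
        assert np.linalg.norm(lf.G @ Qd - F) <= 1e-4 * np.linalg.norm(F)

    def test_zero_map_flagged(self):
        H = SourceDelayMap(H=np.zeros((8, 2)), status="optimal", objective=0.0,
                           residuals=np.zeros(2), rhs_norms=np.zeros(2),
                           delays_ms=np.arange(-4.0, 1.0),
                           modes_V=np.random.default_rng(12).standard_normal((5, 2)))
        img = delay_resolved_image(H)
        assert np.all(img.A == 0) and np.all(np.isnan(img.winning_delay_ms))


class TestCombineChannels:
    def mk(self, A, **kw):
        from emgvestal.solver import SourceImage

        return SourceImage(A=np.asarray(A, float), map_kind="max_over_delays", **kw)

    def test_identical_maps_scale_by_sqrt2(self):
        m = np.array([0.0, 1.0, 2.0])
        out = combine_channels([self.mk(m), self.mk(m)])
        np.testing.assert_allclose(out.A, np.sqrt(2) * m, atol=1e-12)

    def test_zero_map_is_identity_element(self):
        m = np.array([1.0, 0.5, 0.0])
        out = combine_channels([self.mk(m), self.mk(np.zeros(3))])
        np.testing.assert_allclose(out.A, m, atol=1e-12)

    def test_disjoint_one_hot_maps_both_survive(self):
        out = combine_channels([self.mk([3.0, 0.0]), self.mk([0.0, 4.0])])
        np.testing.assert_allclose(out.A, [3.0, 4.0], atol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            combine_channels([self.mk([1.0, 2.0]), self.mk([1.0, 2.0, 3.0])])
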