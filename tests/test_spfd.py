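"""Forward-solver checks: assembly oracles, solver equivalences, physics."""

import numpy as np
import pytest

from ecgloc.conductor_model import VoxelModel, assign_conductivity
from ecgloc.phantom import (AIR, HEART, MUSCLE, PHANTOM_TISSUES, PhantomSpec,
                            make_block_torso)
from ecgloc.spfd import (ConvergenceError, DipoleSource, ForwardSolver,
                         SolverConfig, assemble_system, conducting_node_mask,
                         edge_conductances, electrode_potentials, solve_spfd)


class TestEdgeConductances:
    def test_uniform_interior_closed_form(self):
        sigma = np.full((4, 4, 4), 0.2)
        S = edge_conductances(sigma, pitch_mm=2.0)
        assert S.Sx[1, 2, 2] == pytest.approx(0.2 * 0.002)

    def test_all_air_edge_is_zero(self):
        sigma = np.zeros((3, 3, 3))
        S = edge_conductances(sigma, pitch_mm=2.0)
        assert np.all(S.Sx == 0) and np.all(S.Sy == 0) and np.all(S.Sz == 0)

    def test_mixed_neighborhood_matches_mean_oracle(self):
        # x-edge at (0, 1, 1) touches voxels (0, 0..1, 0..1)
        sigma = np.zeros((1, 2, 2))
        sigma[0, 0, 0], sigma[0, 0, 1] = 0.7, 0.05
        sigma[0, 1, 0], sigma[0, 1, 1] = 0.05, 0.2
        S = edge_conductances(sigma, pitch_mm=2.0)
        oracle = np.mean([0.7, 0.05, 0.05, 0.2]) * 0.002
        assert S.Sx[0, 1, 1] == pytest.approx(oracle)
        assert oracle == pytest.approx(5e-4)

    def test_boundary_edge_averages_existing_voxels_only(self):
        sigma = np.full((2, 2, 2), 0.3)
        S = edge_conductances(sigma, pitch_mm=1.0)
        # corner x-edge (0, 0, 0) touches a single voxel
        assert S.Sx[0, 0, 0] == pytest.approx(0.3 * 0.001)

    def test_randomized_against_enumeration_oracle(self, rng):
        sigma = rng.uniform(0, 1, size=(4, 5, 3))
        S = edge_conductances(sigma, pitch_mm=2.0)
        for _ in range(50):
            ax = rng.integers(3)
            shape = S.along(ax).shape
            e = tuple(rng.integers(0, s) for s in shape)
            t1, t2 = [a for a in range(3) if a != ax]
            vals = []
            for d1 in (-1, 0):
                for d2 in (-1, 0):
                    v = list(e)
                    v[t1] += d1
                    v[t2] += d2
                    if all(0 <= v[a] < sigma.shape[a] for a in range(3)):
                        vals.append(sigma[tuple(v)])
            assert S.along(ax)[e] == pytest.approx(np.mean(vals) * 0.002)


def _uniform_system(n=6, sigma_val=0.2, pitch=2.0, source_node=None, axis="z"):
    sigma = np.zeros((n, n, n))
    sigma[1:-1, 1:-1, 1:-1] = sigma_val
    edges = edge_conductances(sigma, pitch_mm=pitch)
    node = source_node or (n // 2, n // 2, n // 2 - 1)
    return assemble_system(edges, DipoleSource.along(node, axis))


class TestAssembly:
    def test_current_conservation_and_null_space(self):
        sys_ = _uniform_system()
        assert np.sum(sys_.b) == pytest.approx(0.0, abs=1e-18)
        ones = np.ones(sys_.n)
        assert np.max(np.abs(sys_.A @ ones)) < 1e-16
        assert (abs(sys_.A - sys_.A.T)).max() < 1e-18  # symmetric

    def test_matches_hand_assembled_laplacian(self):
        # 3^3 fully conducting block: compare against a brute-force loop
        sigma = np.full((3, 3, 3), 0.5)
        edges = edge_conductances(sigma, pitch_mm=2.0)
        sys_ = assemble_system(edges)
        dims = (4, 4, 4)
        n_nodes = 64
        A_oracle = np.zeros((n_nodes, n_nodes))
        for ax, S in enumerate([edges.Sx, edges.Sy, edges.Sz]):
            for e in np.ndindex(S.shape):
                n0 = np.ravel_multi_index(e, dims)
                e1 = list(e)
                e1[ax] += 1
                n1 = np.ravel_multi_index(tuple(e1), dims)
                s = S[e]
                A_oracle[n0, n0] += s
                A_oracle[n1, n1] += s
                A_oracle[n0, n1] -= s
                A_oracle[n1, n0] -= s
        np.testing.assert_allclose(sys_.A.toarray(), A_oracle, atol=1e-18)

    def test_source_in_air_rejected(self):
        with pytest.raises(ValueError, match="non-conducting"):
            _uniform_system(source_node=(0, 0, 0))

    def test_air_nodes_eliminated(self):
        sigma = np.zeros((4, 4, 4))
        sigma[1:-1, 1:-1, 1:-1] = 0.1
        edges = edge_conductances(sigma, pitch_mm=2.0)
        sys_ = assemble_system(edges)
        assert sys_.n == int(conducting_node_mask(sigma).sum()) == 27


class TestSolver:
    def test_matches_dense_direct_solve(self):
        """MG solution vs dense least-squares oracle on a 6^3 phantom."""
        spec = PhantomSpec(dims=(6, 6, 6), body_margin=1, heart_center=(3, 3, 3),
                           heart_half=2, blood_half=1, lung_halfwidth=1,
                           lung_thickness=1, lung_gap=0)
        model = make_block_torso(spec)
        fs = ForwardSolver(model, SolverConfig(tol=1e-10))
        b = fs.system.rhs_for(DipoleSource.along((3, 3, 3), "x"))
        x_mg, res, _ = fs.mg.solve(b, tol=1e-10)
        x_dense, *_ = np.linalg.lstsq(fs.system.A.toarray(), b, rcond=None)
        x_dense -= x_dense.mean()
        assert np.linalg.norm(x_mg - x_dense) / np.linalg.norm(x_dense) < 1e-5

    def test_gauge_and_residual_contract(self):
        sys_ = _uniform_system()
        field = solve_spfd(sys_, tol=1e-6)
        assert field.residual < 1e-6
        phi_cond = field.phi[field.cond_mask]
        assert abs(phi_cond.mean()) < 1e-12 * np.abs(phi_cond).max()

    def test_mirror_antisymmetry_in_uniform_cube(self):
        # 7^3 conducting body in a 9^3 grid is mirror-symmetric about the
        # z = 4.5 node plane; a z-dipole spanning nodes z = 4, 5 makes the
        # potential antisymmetric under z -> 9 - z
        sigma = np.zeros((9, 9, 9))
        sigma[1:8, 1:8, 1:8] = 0.2
        edges = edge_conductances(sigma, pitch_mm=2.0)
        sys_ = assemble_system(edges, DipoleSource.along((4, 4, 4), "z"))
        field = solve_spfd(sys_, tol=1e-10)
        phi = field.phi
        scale = np.abs(phi).max()
        for z in range(phi.shape[2]):
            np.testing.assert_allclose(phi[:, :, z], -phi[:, :, 9 - z],
                                       atol=1e-8 * scale)

    def test_linearity_and_superposition(self, small_solver):
        s1 = DipoleSource.along((10, 12, 12), "x")
        s2 = DipoleSource.along((13, 12, 13), "y")
        cfg_tol = 1e-10
        f1, _, _ = small_solver.mg.solve(small_solver.system.rhs_for(s1), tol=cfg_tol)
        f2, _, _ = small_solver.mg.solve(small_solver.system.rhs_for(s2), tol=cfg_tol)
        f5, _, _ = small_solver.mg.solve(5.0 * small_solver.system.rhs_for(s1),
                                         tol=cfg_tol)
        f12, _, _ = small_solver.mg.solve(
            small_solver.system.rhs_for(s1) + small_solver.system.rhs_for(s2),
            tol=cfg_tol)
        scale = np.abs(f1).max()
        np.testing.assert_allclose(f5, 5.0 * f1, atol=1e-8 * scale)
        np.testing.assert_allclose(f12, f1 + f2, atol=1e-8 * scale)

    def test_sor_and_multigrid_agree(self):
        spec = PhantomSpec(dims=(16, 16, 16), body_margin=2,
                           heart_center=(8, 8, 8), heart_half=4, blood_half=2,
                           lung_halfwidth=4, lung_thickness=2)
        fs = ForwardSolver(make_block_torso(spec))
        b = fs.system.rhs_for(DipoleSource.along((8, 8, 8), "x"))
        x_mg, _, _ = fs.mg.solve(b, tol=1e-8)
        x_sor, _, _ = fs.mg.solve_sor(b, tol=1e-8)
        assert np.linalg.norm(x_mg - x_sor) / np.linalg.norm(x_mg) < 1e-5

    def test_energy_positivity(self, small_solver, rng):
        for _ in range(5):
            x = rng.standard_normal(small_solver.system.n)
            assert x @ (small_solver.system.A @ x) >= -1e-12

    def test_nonconvergence_raises_with_residual(self):
        sys_ = _uniform_system(n=10)
        with pytest.raises(ConvergenceError) as err:
            solve_spfd(sys_, tol=1e-14, max_iter=1)
        assert err.value.residual > 0

    def test_reciprocity(self, small_model, small_solver):
        """Electrode-pair reading from a dipole equals the dipole-edge
        potential difference from current injected at that electrode pair."""
        e1, e2 = (9, 3, 17), (15, 3, 10)   # two anterior surface nodes
        src = DipoleSource.along((12, 12, 12), "z")
        fa = small_solver.mg.solve(small_solver.system.rhs_for(src), tol=1e-10)[0]
        b = np.zeros(small_solver.system.n)  # raw injection: +1 A at e1, -1 A at e2
        b[small_solver.system.reduced(e1)] += 1.0
        b[small_solver.system.reduced(e2)] -= 1.0
        fb = small_solver.mg.solve(b, tol=1e-10)[0]
        r = small_solver.system.reduced
        lhs = fa[r(e1)] - fa[r(e2)]
        rhs = fb[r(src.anode_node)] - fb[r(src.cathode_node)]
        assert lhs == pytest.approx(rhs, rel=1e-5)


class TestElectrodePotentials:
    def test_zero_field_reads_zero(self, small_model):
        sigma = assign_conductivity(small_model)
        edges = edge_conductances(sigma)
        sys_ = assemble_system(edges)
        from ecgloc.spfd import _field_from_reduced
        field = _field_from_reduced(sys_, np.zeros(sys_.n), 0.0, 0)
        out = electrode_potentials(field, [(12, 3, 12), (3, 12, 12)])
        assert np.all(out == 0.0)

    def test_polarity_swap_negates(self, small_solver):
        n = (12, 12, 12)
        f_pos = small_solver.solve_dipole(DipoleSource.along(n, "x", 1.0))
        f_neg = small_solver.solve_dipole(DipoleSource.along(n, "x", -1.0))
        nodes = [(12, 3, 12), (3, 12, 12), (21, 12, 12)]
        p, m = electrode_potentials(f_pos, nodes), electrode_potentials(f_neg, nodes)
        np.testing.assert_allclose(p, -m, atol=1e-8 * np.abs(p).max())

    def test_electrode_in_air_rejected(self, small_solver):
        field = small_solver.solve_dipole(DipoleSource.along((12, 12, 12), "x"))
        with pytest.raises(ValueError, match="non-conducting"):
            electrode_potentials(field, [(0, 0, 0)])
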