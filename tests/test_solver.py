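"""Equilibrium solver: oracles, symmetry, constraints, objectivity."""

import numpy as np
import pytest

from plaquestress.geometry import Contour
from plaquestress.mesh import FEMesh
from plaquestress.solver import (BoundaryConditions, SolverConfig, SolverError,
                                 apply_rigid_body_constraints, assign_materials,
                                 rigid_body_constraint_matrix, solve_cycle)

from conftest import neohookean_table


def lame_reference(p, ri, ro, G, kappa, r):
    """Closed-form plane-strain thick-walled cylinder (linear elasticity).

    The volumetric penalty acts as the Lame constant lambda = kappa.
    """
    lam = kappa
    nu = lam / (2.0 * (lam + G))
    A = p * ri ** 2 / (ro ** 2 - ri ** 2)
    B = A * ro ** 2
    srr = A - B / r ** 2
    stt = A + B / r ** 2
    szz = nu * (srr + stt)
    vm = np.sqrt(0.5 * ((srr - stt) ** 2 + (stt - szz) ** 2 + (szz - srr) ** 2))
    return srr, stt, szz, vm


def polar_stress(sig, centroids):
    th = np.arctan2(centroids[:, 1], centroids[:, 0])
    c, s = np.cos(th), np.sin(th)
    srr = c * c * sig[:, 0, 0] + 2 * c * s * sig[:, 0, 1] + s * s * sig[:, 1, 1]
    stt = s * s * sig[:, 0, 0] - 2 * c * s * sig[:, 0, 1] + c * c * sig[:, 1, 1]
    return srr, stt


class TestZeroAndSmallLoad:
    def test_zero_load_zero_state(self, annulus_mesh):
        mats = assign_materials(annulus_mesh, neohookean_table())
        steps = solve_cycle(annulus_mesh, mats, 0.0,
                            config=SolverConfig(n_steps=1))
        for s in steps:
            assert np.allclose(s.displacements, 0.0, atol=1e-12)
            assert np.allclose(s.cauchy_stress, 0.0, atol=1e-9)

    def test_negative_load_rejected(self, annulus_mesh):
        mats = assign_materials(annulus_mesh, neohookean_table())
        with pytest.raises(SolverError):
            solve_cycle(annulus_mesh, mats, -1.0)

    def test_linearity_of_small_loads(self, annulus_mesh):
        mats = assign_materials(annulus_mesh, neohookean_table())
        cfg = SolverConfig(n_steps=1)
        vm1 = solve_cycle(annulus_mesh, mats, 0.1, config=cfg)[-1].von_mises.max()
        vm2 = solve_cycle(annulus_mesh, mats, 0.2, config=cfg)[-1].von_mises.max()
        assert vm2 / vm1 == pytest.approx(2.0, rel=0.01)


class TestLameOracle:
    def test_inner_wall_stress(self, lame_case):
        mesh, steps = lame_case["mesh"], lame_case["steps"]
        sup = mesh.superficial_set
        cent = mesh.centroids()[sup]
        r = np.hypot(cent[:, 0], cent[:, 1])
        srr_fe, stt_fe = polar_stress(steps[-1].cauchy_stress[sup], cent)
        vm_fe = steps[-1].von_mises[sup]
        _, stt_o, _, vm_o = lame_reference(lame_case["pressure"], lame_case["ri"],
                                           lame_case["ro"], lame_case["G"],
                                           lame_case["kappa"], r.mean())
        assert np.mean(stt_fe) == pytest.approx(stt_o, rel=0.02)
        assert np.mean(vm_fe) == pytest.approx(vm_o, rel=0.02)

    def test_equilibrium_residual(self, lame_case):
        s = lame_case["steps"][-1]
        assert s.residual_norm <= 1e-7 * max(lame_case["pressure"], 1.0)

    def test_axisymmetric_solution_is_symmetric(self, lame_case):
        """Angular sector means of von Mises agree to <1% (near the lumen)."""
        mesh, steps = lame_case["mesh"], lame_case["steps"]
        cent = mesh.centroids()
        r = np.hypot(cent[:, 0], cent[:, 1])
        band = (r > 1.5) & (r < 1.8)
        th = np.arctan2(cent[band, 1], cent[band, 0])
        vm = steps[-1].von_mises[band]
        sector = ((th + np.pi) / (2 * np.pi) * 36).astype(int) % 36
        means = np.array([vm[sector == k].mean() for k in range(36)])
        assert means.std() / means.mean() < 0.01

    def test_centroid_stays_fixed(self, lame_case):
        u = lame_case["steps"][-1].displacements
        assert np.abs(u.mean(axis=0)).max() < 1e-9

    def test_dpss_location_superficial(self, lame_case):
        from plaquestress.metrics import compute_dpss
        mesh = lame_case["mesh"]
        dpss, xy, elem = compute_dpss(lame_case["steps"], mesh.superficial_set,
                                      mesh)
        r = np.hypot(*xy)
        assert r < 1.5 + 0.055  # on or within ~50 um of the lumen wall


class TestRigidBodyConstraints:
    def test_constraint_matrix_removes_exactly_three_modes(self, annulus_mesh):
        C = rigid_body_constraint_matrix(annulus_mesh.nodes)
        assert C.shape == (3, 2 * annulus_mesh.n_nodes)
        assert np.linalg.matrix_rank(C.toarray()) == 3
        # a pure translation violates the first two rows, a rotation the third
        N = annulus_mesh.n_nodes
        u_t = np.tile([1.0, 0.0], N)
        assert abs((C @ u_t)[0]) > 1e-9
        c = annulus_mesh.nodes - annulus_mesh.nodes.mean(axis=0)
        u_r = np.column_stack([-c[:, 1], c[:, 0]]).ravel()
        assert abs((C @ u_r)[2]) > 1e-9
        # radial breathing satisfies all constraints (deformation left free)
        u_b = c.ravel()
        assert np.abs(C @ u_b).max() < 1e-9

    def test_augmentation_shape(self, annulus_mesh):
        import scipy.sparse as sp
        n = 2 * annulus_mesh.n_nodes
        K = sp.eye(n, format="csr")
        C = rigid_body_constraint_matrix(annulus_mesh.nodes)
        Kaug, Raug = apply_rigid_body_constraints(K, np.zeros(n), C)
        assert Kaug.shape == (n + 3, n + 3) and len(Raug) == n + 3

    def test_solution_satisfies_constraints(self, lame_case):
        u = lame_case["steps"][-1].displacements
        nodes = lame_case["mesh"].nodes
        c = nodes - nodes.mean(axis=0)
        moment = float(np.sum(c[:, 0] * u[:, 1] - c[:, 1] * u[:, 0]))
        assert abs(moment) < 1e-8
        assert np.abs(u.sum(axis=0)).max() < 1e-8


class TestObjectivity:
    def test_rotated_problem_rotates_solution(self, lame_case):
        """Rotating the reference mesh by 30 deg rotates u; peak stress invariant."""
        mesh, steps = lame_case["mesh"], lame_case["steps"]
        th = np.radians(30.0)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = FEMesh(nodes=mesh.nodes @ Q.T, elements=mesh.elements.copy(),
                     labels=mesh.labels.copy(),
                     lumen_edges=mesh.lumen_edges.copy(),
                     outer_edges=mesh.outer_edges.copy(),
                     superficial_set=mesh.superficial_set.copy())
        mats = assign_materials(rot, neohookean_table())
        steps_rot = solve_cycle(rot, mats, lame_case["pressure"],
                                config=SolverConfig(n_steps=2))
        u_exp = steps[-1].displacements @ Q.T
        err = np.abs(steps_rot[-1].displacements - u_exp).max()
        assert err < 5e-3 * np.abs(u_exp).max() + 1e-12
        vm0 = steps[-1].von_mises[mesh.superficial_set].max()
        vm1 = steps_rot[-1].von_mises[rot.superficial_set].max()
        assert vm1 == pytest.approx(vm0, rel=5e-3)
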