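"""Quasi-static large-deformation equilibrium of a loaded cross-section.

The cross-section is modelled in plane strain with constant-strain triangles
under a follower pressure acting on the (deformed) lumen boundary.  The
imaged, diastolic geometry is the stress-free reference configuration: the
solver ramps the *relative* pressure from zero to its systolic peak in
monotone increments, solving each with Newton iterations; elasticity makes
intermediate unloading redundant, so the diastolic (zero-load) and peak
states bracket the lumen-diameter extremes over the cycle.

Numerics
--------
* Deviatoric response: analytic first Piola-Kirchhoff stress of the
  hyperelastic models; the element tangent is a central finite difference of
  the element force (exactly consistent with the residual by construction).
* Near-incompressibility: the volumetric penalty kappa (J - 1)^2 / 2 is
  evaluated on the *average nodal* Jacobian (volume-weighted mean of the
  element J around each node).  Plain per-element penalties lock linear
  triangles volumetrically; nodal averaging restores the correct compliant
  response at negligible cost.
* Rigid-body motion: the pressure load is self-equilibrated, so translations
  and the in-plane rotation are removed by three Lagrange-multiplier
  constraints (zero mean translation, zero mean moment of displacement) —
  rotation is restricted to keep the section from rolling while leaving the
  radial deformation free.
* Diverging steps are bisected automatically (up to ``max_bisect`` levels).

Units: mm, kPa; forces are kPa*mm = mN per mm of out-of-plane thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import Contour
from .materials import (HolzapfelParams, KinematicState, _second_pk_iso,
                        material_for_region, penalty_for)
from .mesh import FEMesh
from .pressure import PressureLoad

__all__ = [
    "SolverConfig",
    "BoundaryConditions",
    "SolutionStep",
    "SolverError",
    "MaterialAssignment",
    "assign_materials",
    "rigid_body_constraint_matrix",
    "apply_rigid_body_constraints",
    "solve_cycle",
]

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    n_steps: int = 10
    newton_rel_tol: float = 1e-8
    newton_abs_tol: float = 1e-10
    max_newton_iter: int = 30
    max_bisect: int = 5
    follower_load: bool = True
    kappa_factor: float = 1000.0  # penalty modulus / material shear scale
    fd_step: float = 1e-6         # mm, tangent finite-difference step


@dataclass
class BoundaryConditions:
    """Pressure-loaded lumen edges plus the rigid-body constraint."""

    pressure_edges: np.ndarray           # (L, 2) node pairs, CCW around the lumen
    constrain_translation: bool = True
    constrain_rotation: bool = True


@dataclass
class SolutionStep:
    load_fraction: float
    pressure: float                       # kPa applied at this step
    displacements: np.ndarray             # (N, 2) mm
    cauchy_stress: np.ndarray             # (M, 3, 3) kPa at element centroids
    von_mises: np.ndarray                 # (M,) kPa
    deformed_lumen: Contour
    newton_iterations: int = 0
    residual_norm: float = 0.0


@dataclass
class MaterialAssignment:
    """Per-element material resolution for one mesh."""

    groups: list = field(default_factory=list)  # (element_ids, params)
    kappa: np.ndarray = None                    # (M,) penalty modulus per element
    fiber: np.ndarray = None                    # (M, 2) circumferential direction
    table: dict = None


def assign_materials(mesh: FEMesh, table: dict | None = None,
                     kappa_factor: float = 1000.0) -> MaterialAssignment:
    """Resolve mesh labels to material parameters, penalties and fiber directions.

    The single fiber family of the anisotropic layers runs circumferentially:
    perpendicular to the ray from the lumen centroid in the reference state.
    """
    M = mesh.n_elements
    kappa = np.zeros(M)
    groups = []
    for label in np.unique(mesh.labels):
        ids = np.flatnonzero(mesh.labels == label)
        params = material_for_region(str(label), table)
        groups.append((ids, params))
        kappa[ids] = penalty_for(params, kappa_factor).kappa
    center = mesh.nodes[mesh.lumen_loop()].mean(axis=0)
    ray = mesh.centroids() - center
    ray /= np.linalg.norm(ray, axis=1, keepdims=True)
    fiber = np.column_stack([-ray[:, 1], ray[:, 0]])
    return MaterialAssignment(groups=groups, kappa=kappa, fiber=fiber, table=table)


# ---------------------------------------------------------------------------
# assembly machinery
# ---------------------------------------------------------------------------

class _Assembler:
    def __init__(self, mesh: FEMesh, mats: MaterialAssignment, cfg: SolverConfig):
        self.mesh = mesh
        self.mats = mats
        self.cfg = cfg
        X = mesh.coords()                      # (M, 3, 2)
        self.A0 = mesh.areas()
        # CST shape-function gradients g_a (M, 3, 2)
        G = np.empty_like(X)
        for a in range(3):
            b, c = (a + 1) % 3, (a + 2) % 3
            G[:, a, 0] = X[:, b, 1] - X[:, c, 1]
            G[:, a, 1] = X[:, c, 0] - X[:, b, 0]
        self.G = G / (2.0 * self.A0)[:, None, None]
        self.w = self.A0 / 3.0                 # nodal volume weight per corner

        N = mesh.n_nodes
        conn = mesh.elements
        self.V_n = np.bincount(conn.ravel(), np.repeat(self.w, 3), minlength=N)
        self.K_n = np.bincount(conn.ravel(), np.repeat(self.w * mats.kappa, 3),
                               minlength=N)
        # sparsity pattern for the element-local blocks (6x6 per element)
        dofs = np.stack([2 * conn, 2 * conn + 1], axis=2).reshape(-1, 6)  # (M, 6)
        self.edofs = dofs
        self.rows66 = np.repeat(dofs, 6, axis=1).ravel()
        self.cols66 = np.tile(dofs, (1, 6)).ravel()
        self.ndof = 2 * N

    # -- kinematics -----------------------------------------------------
    def deformation_gradient(self, ue: np.ndarray) -> np.ndarray:
        return np.eye(2) + np.einsum("mai,maj->mij", ue, self.G)

    # -- deviatoric internal force --------------------------------------
    def _p_inplane(self, F: np.ndarray) -> np.ndarray:
        """In-plane block of the isochoric PK1 stress, (M, 2, 2)."""
        P = np.empty_like(F)
        for ids, params in self.mats.groups:
            fiber = self.mats.fiber[ids] if isinstance(params, HolzapfelParams) else None
            st = KinematicState(F[ids], fiber=fiber)
            S = _second_pk_iso(st, params)
            P[ids] = np.einsum("mik,mkj->mij", F[ids], S[:, :2, :2])
        return P

    def f_dev(self, ue: np.ndarray) -> np.ndarray:
        """Deviatoric element force, (M, 3, 2)."""
        F = self.deformation_gradient(ue)
        P = self._p_inplane(F)
        return self.A0[:, None, None] * np.einsum("mij,maj->mai", P, self.G)

    # -- volumetric (average nodal pressure) -----------------------------
    def _jacobians(self, ue: np.ndarray):
        F = self.deformation_gradient(ue)
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        cof = np.empty_like(F)
        cof[:, 0, 0] = F[:, 1, 1]
        cof[:, 0, 1] = -F[:, 1, 0]
        cof[:, 1, 0] = -F[:, 0, 1]
        cof[:, 1, 1] = F[:, 0, 0]
        dJ = np.einsum("mij,maj->mai", cof, self.G)   # dJ/du_(a,i)
        return J, dJ

    def nodal_jbar(self, ue: np.ndarray) -> np.ndarray:
        J, _ = self._jacobians(ue)
        conn = self.mesh.elements
        num = np.bincount(conn.ravel(), np.repeat(self.w * J, 3), minlength=self.mesh.n_nodes)
        return num / self.V_n

    def _vol_gmat(self, dJ: np.ndarray) -> sp.csr_matrix:
        """Sparse (n_nodes x ndof) matrix of dJbar_n / du."""
        conn = self.mesh.elements
        M = self.mesh.n_elements
        # entry (row n_a, col dof (b, k)): w_e / V_{n_a} * dJ[b, k]
        rows = np.broadcast_to(conn[:, :, None, None], (M, 3, 3, 2))
        cols = np.broadcast_to((2 * conn[:, None, :, None]
                                + np.arange(2)[None, None, None, :]), (M, 3, 3, 2))
        vals = np.broadcast_to((self.w[:, None, None, None]
                                * dJ[:, None, :, :]), (M, 3, 3, 2)).copy()
        vals /= self.V_n[rows]
        return sp.csr_matrix((vals.ravel(), (rows.ravel(), cols.ravel())),
                             shape=(self.mesh.n_nodes, self.ndof))

    def vol_force_tangent(self, ue: np.ndarray, want_tangent: bool):
        J, dJ = self._jacobians(ue)
        conn = self.mesh.elements
        N = self.mesh.n_nodes
        num = np.bincount(conn.ravel(), np.repeat(self.w * J, 3), minlength=N)
        Jbar = num / self.V_n
        t_n = self.K_n * (Jbar - 1.0)
        Gmat = self._vol_gmat(dJ)
        f = Gmat.T @ t_n                                        # (ndof,)
        if not want_tangent:
            return f, None
        K1 = (Gmat.T @ sp.diags(self.K_n)) @ Gmat
        # geometric term: c_e * d2J/du2, c_e = w_e * sum_a t_n/V_n at element nodes
        c_e = self.w * (t_n / self.V_n)[conn].sum(axis=1)
        # d2J/du_ai du_bk = eps_ik * (G_a1 G_b2 - G_a2 G_b1)
        m_ab = (self.G[:, :, None, 0] * self.G[:, None, :, 1]
                - self.G[:, :, None, 1] * self.G[:, None, :, 0])  # (M, 3, 3)
        eps = np.array([[0.0, 1.0], [-1.0, 0.0]])
        blk = c_e[:, None, None, None, None] * m_ab[:, :, None, :, None] \
            * eps[None, None, :, None, :]                        # (M, a, i, b, k)
        K2 = sp.csr_matrix((blk.reshape(len(c_e), 36).ravel(),
                            (self.rows66, self.cols66)),
                           shape=(self.ndof, self.ndof))
        return f, K1 + K2

    # -- global internal force and tangent -------------------------------
    def internal(self, u: np.ndarray, want_tangent: bool):
        ue = u[self.mesh.elements]                              # (M, 3, 2)
        fd = self.f_dev(ue)
        f = np.zeros(self.ndof)
        np.add.at(f, (2 * self.mesh.elements[..., None]
                      + np.arange(2)).ravel(), fd.ravel())
        fv, Kv = self.vol_force_tangent(ue, want_tangent)
        f += fv
        if not want_tangent:
            return f, None
        # deviatoric tangent: central FD of the element force
        h = self.cfg.fd_step
        Kblk = np.empty((self.mesh.n_elements, 6, 6))
        for d in range(6):
            b, k = divmod(d, 2)
            up = ue.copy(); up[:, b, k] += h
            um = ue.copy(); um[:, b, k] -= h
            Kblk[:, :, d] = ((self.f_dev(up) - self.f_dev(um)) / (2 * h)).reshape(-1, 6)
        Kd = sp.csr_matrix((Kblk.ravel(), (self.rows66, self.cols66)),
                           shape=(self.ndof, self.ndof))
        return f, Kd + Kv

    # -- follower pressure ------------------------------------------------
    def external(self, u: np.ndarray, p: float, edges: np.ndarray,
                 follower: bool, want_tangent: bool):
        x = self.mesh.nodes + (u if follower else 0.0)
        i1, i2 = edges[:, 0], edges[:, 1]
        dx = x[i2] - x[i1]
        # CCW lumen loop: interior on the left; the wall-facing normal is
        # (dy, -dx) and the pressure pushes the wall outward along it.
        fe = 0.5 * p * np.column_stack([dx[:, 1], -dx[:, 0]])   # per node
        f = np.zeros(self.ndof)
        for idx in (i1, i2):
            np.add.at(f, 2 * idx, fe[:, 0])
            np.add.at(f, 2 * idx + 1, fe[:, 1])
        if not (want_tangent and follower):
            return f, None
        # d fe / d (x1, y1, x2, y2); same force goes to both edge nodes
        base = 0.5 * p * np.array([[0.0, -1.0, 0.0, 1.0],
                                   [1.0, 0.0, -1.0, 0.0]])
        L = len(edges)
        edofs = np.column_stack([2 * i1, 2 * i1 + 1, 2 * i2, 2 * i2 + 1])  # (L, 4)
        rows, cols, vals = [], [], []
        for recv in (i1, i2):
            rdof = np.column_stack([2 * recv, 2 * recv + 1])    # (L, 2)
            rows.append(np.repeat(rdof, 4, axis=1).ravel())
            cols.append(np.tile(edofs, (1, 2)).ravel())
            vals.append(np.tile(base.ravel(), L))
        K = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(self.ndof, self.ndof))
        return f, K

    # -- postprocessing ----------------------------------------------------
    def element_stress(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress (M, 3, 3): isochoric response + average nodal pressure."""
        ue = u[self.mesh.elements]
        F = self.deformation_gradient(ue)
        sig = np.empty((self.mesh.n_elements, 3, 3))
        for ids, params in self.mats.groups:
            fiber = self.mats.fiber[ids] if isinstance(params, HolzapfelParams) else None
            st = KinematicState(F[ids], fiber=fiber)
            S = _second_pk_iso(st, params)
            F3 = np.zeros((len(ids), 3, 3))
            F3[:, :2, :2] = F[ids]
            F3[:, 2, 2] = 1.0
            sig[ids] = np.einsum("mik,mkl,mjl->mij", F3, S, F3) / st.J[:, None, None]
        Jbar = self.nodal_jbar(ue)
        p_n = (self.K_n / self.V_n) * (Jbar - 1.0)
        p_e = p_n[self.mesh.elements].mean(axis=1)
        sig += p_e[:, None, None] * np.eye(3)
        return sig


# ---------------------------------------------------------------------------
# rigid-body constraints
# ---------------------------------------------------------------------------

def rigid_body_constraint_matrix(nodes: np.ndarray,
                                 translation: bool = True,
                                 rotation: bool = True) -> sp.csr_matrix:
    """Constraint rows removing mean translation and mean rotation.

    Rows: sum(u_x) = 0, sum(u_y) = 0, sum(x0 cross u) = 0 over all nodes —
    exactly the three in-plane rigid modes and nothing else.
    """
    N = len(nodes)
    rows = []
    if translation:
        rx = np.zeros(2 * N); rx[0::2] = 1.0 / N
        ry = np.zeros(2 * N); ry[1::2] = 1.0 / N
        rows += [rx, ry]
    if rotation:
        c = nodes - nodes.mean(axis=0)
        scale = max(np.abs(c).max(), 1e-12)
        rr = np.zeros(2 * N)
        rr[0::2] = -c[:, 1] / (N * scale)
        rr[1::2] = c[:, 0] / (N * scale)
        rows.append(rr)
    if not rows:
        raise SolverError("no rigid-body constraints requested")
    return sp.csr_matrix(np.vstack(rows))


def apply_rigid_body_constraints(K: sp.spmatrix, R: np.ndarray,
                                 C: sp.spmatrix):
    """Augment the Newton system with Lagrange multiplier rows.

    Returns the KKT matrix [[K, C^T], [C, 0]] and the extended right-hand
    side; raises if the augmented system is structurally rank deficient.
    """
    m = C.shape[0]
    Kaug = sp.bmat([[K, C.T], [C, None]], format="csc")
    Raug = np.concatenate([R, np.zeros(m)])
    if Kaug.shape[0] != K.shape[0] + m:
        raise SolverError("constraint augmentation failed")
    return Kaug, Raug


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _newton(assem: _Assembler, u0, lam0, p, bc, cfg):
    u, lam = u0.copy(), lam0.copy()
    C = rigid_body_constraint_matrix(assem.mesh.nodes, bc.constrain_translation,
                                     bc.constrain_rotation)
    edges = bc.pressure_edges
    fext_ref = None
    for it in range(cfg.max_newton_iter):
        fint, K = assem.internal(u.reshape(-1, 2), want_tangent=True)
        fext, Kext = assem.external(u.reshape(-1, 2), p, edges,
                                    cfg.follower_load, want_tangent=True)
        if fext_ref is None:
            fext_ref = max(float(np.linalg.norm(fext)), 0.0)
        R = fint - fext + C.T @ lam
        rnorm = float(np.linalg.norm(R))
        tol = max(cfg.newton_rel_tol * fext_ref, cfg.newton_abs_tol)
        gap = float(np.linalg.norm(C @ u))
        if rnorm <= tol and gap <= 1e-12 + 1e-9 * (np.abs(u).max() + 1.0):
            return u, lam, it, rnorm
        Ktot = K - Kext if Kext is not None else K
        Kaug, Raug = apply_rigid_body_constraints(Ktot.tocsc(), R, C)
        rhs = -Raug
        rhs[len(R):] = -(C @ u)
        try:
            sol = spsolve(Kaug.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular systems
            raise SolverError(f"linear solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("Newton update is not finite")
        u = u + sol[:len(u)]
        lam = lam + sol[len(u):]
        # guard against inverted elements
        F = assem.deformation_gradient(u.reshape(-1, 2)[assem.mesh.elements])
        if np.any(F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0] <= 0):
            raise SolverError("element inversion during Newton update")
    raise SolverError(f"Newton failed to converge at p={p:.4g} kPa "
                      f"(residual {rnorm:.3g})")


def solve_cycle(mesh: FEMesh, materials: MaterialAssignment,
                load: PressureLoad | float,
                bc: BoundaryConditions | None = None,
                config: SolverConfig | None = None) -> list[SolutionStep]:
    """Ramp the relative pressure to its peak and return all converged steps.

    ``load`` may be a :class:`PressureLoad` (its peak is used) or a plain peak
    pressure in kPa.  Step 0 is always the stress-free diastolic state.
    """
    cfg = config or SolverConfig()
    if bc is None:
        bc = BoundaryConditions(pressure_edges=mesh.lumen_edges)
    peak = load.peak if isinstance(load, PressureLoad) else float(load)
    if peak < 0:
        raise SolverError("peak relative pressure must be >= 0")

    assem = _Assembler(mesh, materials, cfg)
    nC = int(bc.constrain_translation) * 2 + int(bc.constrain_rotation)
    u = np.zeros(assem.ndof)
    lam = np.zeros(nC)

    fractions = np.linspace(0.0, 1.0, cfg.n_steps + 1)
    steps: list[SolutionStep] = []
    loop = mesh.lumen_loop()

    def _record(frac, p, u, iters, rnorm):
        sig = assem.element_stress(u.reshape(-1, 2))
        vm = _von_mises_batch(sig)
        lum = Contour(mesh.nodes[loop] + u.reshape(-1, 2)[loop])
        steps.append(SolutionStep(load_fraction=float(frac), pressure=float(p),
                                  displacements=u.reshape(-1, 2).copy(),
                                  cauchy_stress=sig, von_mises=vm,
                                  deformed_lumen=lum, newton_iterations=iters,
                                  residual_norm=rnorm))

    _record(0.0, 0.0, u, 0, 0.0)
    cur = 0.0
    for frac in fractions[1:]:
        target, level = frac, 0
        iters = rnorm = 0
        while cur < frac - 1e-12:
            try:
                u_new, lam_new, iters, rnorm = _newton(
                    assem, u, lam, peak * target, bc, cfg)
                u, lam = u_new, lam_new
                cur = target
                target = frac
            except SolverError:
                level += 1
                if level > cfg.max_bisect:
                    raise SolverError(
                        "step bisection exhausted; last converged load "
                        f"fraction {cur:.4f}") from None
                target = cur + (target - cur) / 2.0
        _record(frac, peak * frac, u, iters, rnorm)
    return steps


def _von_mises_batch(sig: np.ndarray) -> np.ndarray:
    tr = np.trace(sig, axis1=-2, axis2=-1)
    dev = sig - (tr / 3.0)[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
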