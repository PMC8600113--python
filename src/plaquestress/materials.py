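"""Hyperelastic tissue models for the vessel wall.

Two strain-energy density functions cover the five wall materials:

* isotropic exponential Mooney-Rivlin for the soft/stiff intimal inclusions
  (lipid pool, calcium deposit)::

      W = C1 (I1 - 3) + C2 (I2 - 3) + D1 (exp(D2 (I1 - 3)) - 1)

* a two-term Holzapfel-type fiber-reinforced model for the load-bearing
  layers (fibrous intima, media, adventitia)::

      W = mu (I1 - 3) + (k1 / k2) (exp{k2 [(1 - rho) (I1 - 3)^2
                                           + rho (I4 - 1)^2]} - 1)

  where I4 = a . C a is the squared stretch along the reference fiber
  direction a (a single in-plane circumferential family; a 2D plane-strain
  model cannot carry out-of-plane helical pairs) and rho in [0, 1] weights
  the anisotropic contribution.

Kinematics are plane-strain finite deformation: the in-plane deformation
gradient F (2x2) is embedded in 3D with out-of-plane stretch 1, so the
invariants and the Cauchy stress (including sigma_zz) are computed from the
full 3D tensors.  The deviatoric response is evaluated on isochoric
invariants (J^{-2/3}-scaled); near-incompressibility is imposed by a
volumetric penalty kappa (J - 1)^2 / 2, which stands in for the mixed
("hybrid") displacement-pressure elements of commercial codes.

Stresses and moduli are in kPa, consistent with pressures in kPa and
lengths in mm (forces then come out in mN per mm out-of-plane thickness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MooneyRivlinParams",
    "HolzapfelParams",
    "VolumetricPenalty",
    "KinematicState",
    "mooney_rivlin_energy",
    "holzapfel_energy",
    "cauchy_stress",
    "pk1_stress",
    "total_energy",
    "material_for_region",
    "default_material_table",
    "penalty_for",
    "ANISOTROPIC_LABELS",
    "ISOTROPIC_LABELS",
]

_EXP_LIMIT = 60.0  # exp argument beyond which the model is declared blown up

ISOTROPIC_LABELS = ("lipid", "calcium")
ANISOTROPIC_LABELS = ("fibrous", "media", "adventitia")


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Exponential Mooney-Rivlin constants (c1, c2, d1 in kPa; d2 unitless)."""

    c1: float
    c2: float = 0.0
    d1: float = 0.0
    d2: float = 0.0

    def __post_init__(self):
        vals = (self.c1, self.c2, self.d1, self.d2)
        if not all(np.isfinite(vals)):
            raise ValueError("Mooney-Rivlin parameters must be finite")
        if self.c1 + self.c2 <= 0 and self.d1 * self.d2 <= 0:
            raise ValueError("Mooney-Rivlin parameters give zero stiffness")

    @property
    def shear_scale(self) -> float:
        """Leading small-strain shear-modulus scale, kPa."""
        return 2.0 * (self.c1 + self.c2 + self.d1 * self.d2)


@dataclass(frozen=True)
class HolzapfelParams:
    """Two-term Holzapfel constants (mu, k1 in kPa; k2, rho unitless)."""

    mu: float
    k1: float
    k2: float
    rho: float
    tension_only: bool = True  # fiber term active only for I4 >= 1

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")

    @property
    def shear_scale(self) -> float:
        return 2.0 * self.mu + self.k1


@dataclass(frozen=True)
class VolumetricPenalty:
    """Bulk-like penalty modulus kappa (kPa) enforcing near-incompressibility."""

    kappa: float

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def penalty_for(material, factor: float = 1000.0) -> VolumetricPenalty:
    """Penalty modulus scaled to the material's leading shear scale."""
    return VolumetricPenalty(factor * material.shear_scale)


class KinematicState:
    """Plane-strain kinematic quantities derived from in-plane F (..., 2, 2).

    ``fiber`` is the reference fiber direction, a unit 2-vector (or an array
    broadcastable to the batch) used for I4; it may be omitted for isotropic
    materials.
    """

    def __init__(self, F: np.ndarray, fiber: np.ndarray | None = None):
        F = np.asarray(F, float)
        if F.shape[-2:] != (2, 2):
            raise ValueError("F must have shape (..., 2, 2)")
        self.F = F
        self.J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(self.J <= 0):
            raise ValueError("non-positive det(F): element inversion")
        # 3D right Cauchy-Green with out-of-plane stretch 1
        C2 = np.einsum("...ki,...kj->...ij", F, F)
        self.C2 = C2
        self.I1 = C2[..., 0, 0] + C2[..., 1, 1] + 1.0
        detC2 = self.J ** 2
        # I2 of the 3D C with C33 = 1: I2 = det(C2) + tr(C2)
        self.I2 = detC2 + C2[..., 0, 0] + C2[..., 1, 1]
        if fiber is not None:
            a = np.asarray(fiber, float)
            a = a / np.linalg.norm(a, axis=-1, keepdims=True)
            self.fiber = np.broadcast_to(a, F.shape[:-2] + (2,))
            self.I4 = np.einsum("...i,...ij,...j->...", self.fiber, C2, self.fiber)
        else:
            self.fiber = None
            self.I4 = np.ones_like(self.J)
        # isochoric invariants
        Jm23 = self.J ** (-2.0 / 3.0)
        self.I1_bar = Jm23 * self.I1
        self.I2_bar = Jm23 ** 2 * self.I2
        self.I4_bar = Jm23 * self.I4

    @classmethod
    def identity(cls, fiber=(1.0, 0.0)) -> "KinematicState":
        return cls(np.eye(2), fiber=np.asarray(fiber))


def _checked_exp(arg: np.ndarray, what: str) -> np.ndarray:
    if np.any(arg > _EXP_LIMIT):
        raise OverflowError(
            f"exponential overflow in {what}: max argument {np.max(arg):.3g}")
    return np.exp(arg)


def mooney_rivlin_energy(state: KinematicState, p: MooneyRivlinParams) -> np.ndarray:
    """Isochoric strain-energy density (kPa) of the exponential Mooney-Rivlin model."""
    e1 = state.I1_bar - 3.0
    e2 = state.I2_bar - 3.0
    W = p.c1 * e1 + p.c2 * e2
    if p.d1 != 0.0:
        W = W + p.d1 * (_checked_exp(p.d2 * e1, f"D2*(I1-3) with D2={p.d2}") - 1.0)
    return W


def holzapfel_energy(state: KinematicState, p: HolzapfelParams) -> np.ndarray:
    """Isochoric strain-energy density (kPa) of the two-term Holzapfel model."""
    e1 = state.I1_bar - 3.0
    e4 = state.I4_bar - 1.0
    if p.tension_only:
        e4 = np.maximum(e4, 0.0)  # collagen carries tension only
    Q = (1.0 - p.rho) * e1 ** 2 + p.rho * e4 ** 2
    return p.mu * e1 + (p.k1 / p.k2) * (_checked_exp(p.k2 * Q, "k2*Q (Holzapfel)") - 1.0)


def _dW_dinvariants(state: KinematicState, material):
    """(W1, W2, W4) = partial derivatives of W w.r.t. isochoric I1, I2, I4."""
    shape = state.J.shape
    if isinstance(material, MooneyRivlinParams):
        e1 = state.I1_bar - 3.0
        W1 = np.full(shape, material.c1, float)
        if material.d1 != 0.0:
            W1 = W1 + material.d1 * material.d2 * _checked_exp(
                material.d2 * e1, f"D2*(I1-3) with D2={material.d2}")
        W2 = np.full(shape, material.c2, float)
        W4 = np.zeros(shape)
    elif isinstance(material, HolzapfelParams):
        e1 = state.I1_bar - 3.0
        e4 = state.I4_bar - 1.0
        if material.tension_only:
            e4 = np.maximum(e4, 0.0)
        Q = (1.0 - material.rho) * e1 ** 2 + material.rho * e4 ** 2
        E = _checked_exp(material.k2 * Q, "k2*Q (Holzapfel)")
        W1 = material.mu + 2.0 * material.k1 * (1.0 - material.rho) * e1 * E
        W2 = np.zeros(shape)
        W4 = 2.0 * material.k1 * material.rho * e4 * E
    else:
        raise TypeError(f"unknown material type {type(material).__name__}")
    return W1, W2, W4


def _second_pk_iso(state: KinematicState, material) -> np.ndarray:
    """Isochoric second Piola-Kirchhoff stress, full 3D (..., 3, 3)."""
    W1, W2, W4 = _dW_dinvariants(state, material)
    n = state.J.shape
    C3 = np.zeros(n + (3, 3))
    C3[..., :2, :2] = state.C2
    C3[..., 2, 2] = 1.0
    C3inv = np.zeros_like(C3)
    # block inverse: C2 and the unit out-of-plane entry
    det2 = state.J ** 2
    C3inv[..., 0, 0] = state.C2[..., 1, 1] / det2
    C3inv[..., 1, 1] = state.C2[..., 0, 0] / det2
    C3inv[..., 0, 1] = -state.C2[..., 0, 1] / det2
    C3inv[..., 1, 0] = -state.C2[..., 1, 0] / det2
    C3inv[..., 2, 2] = 1.0
    I3 = np.broadcast_to(np.eye(3), C3.shape)

    Jm23 = (state.J ** (-2.0 / 3.0))[..., None, None]
    I1 = state.I1[..., None, None]
    I2 = state.I2[..., None, None]
    I4 = state.I4[..., None, None]
    dI1 = Jm23 * (I3 - (I1 / 3.0) * C3inv)
    dI2 = Jm23 ** 2 * (I1 * I3 - C3 - (2.0 * I2 / 3.0) * C3inv)
    S = 2.0 * (W1[..., None, None] * dI1 + W2[..., None, None] * dI2)
    if state.fiber is not None and np.any(W4 != 0):
        A = np.zeros(n + (3, 3))
        A[..., :2, :2] = np.einsum("...i,...j->...ij", state.fiber, state.fiber)
        dI4 = Jm23 * (A - (I4 / 3.0) * C3inv)
        S = S + 2.0 * W4[..., None, None] * dI4
    return S


def _embed3(F2: np.ndarray) -> np.ndarray:
    F3 = np.zeros(F2.shape[:-2] + (3, 3))
    F3[..., :2, :2] = F2
    F3[..., 2, 2] = 1.0
    return F3


def cauchy_stress(state: KinematicState, material,
                  penalty: VolumetricPenalty) -> np.ndarray:
    """Cauchy stress (..., 3, 3) in kPa, deviatoric response plus penalty pressure.

    sigma = (1/J) F S_iso F^T + kappa (J - 1) I.  The out-of-plane component
    sigma_zz produced by the plane-strain constraint is included.
    """
    S = _second_pk_iso(state, material)
    F3 = _embed3(state.F)
    sig = np.einsum("...ik,...kl,...jl->...ij", F3, S, F3) / state.J[..., None, None]
    p_vol = penalty.kappa * (state.J - 1.0)
    sig = sig + p_vol[..., None, None] * np.eye(3)
    return sig


def pk1_stress(state: KinematicState, material,
               penalty: VolumetricPenalty | None = None) -> np.ndarray:
    """First Piola-Kirchhoff stress, full 3D (..., 3, 3), kPa."""
    S = _second_pk_iso(state, material)
    if penalty is not None:
        # S_vol = J p C^{-1} with p = kappa (J - 1)
        n = state.J.shape
        det2 = state.J ** 2
        C3inv = np.zeros(n + (3, 3))
        C3inv[..., 0, 0] = state.C2[..., 1, 1] / det2
        C3inv[..., 1, 1] = state.C2[..., 0, 0] / det2
        C3inv[..., 0, 1] = -state.C2[..., 0, 1] / det2
        C3inv[..., 1, 0] = -state.C2[..., 1, 0] / det2
        C3inv[..., 2, 2] = 1.0
        p = penalty.kappa * (state.J - 1.0)
        S = S + (state.J * p)[..., None, None] * C3inv
    return np.einsum("...ik,...kj->...ij", _embed3(state.F), S)


def total_energy(state: KinematicState, material,
                 penalty: VolumetricPenalty | None = None) -> np.ndarray:
    """Total strain-energy density: isochoric part plus volumetric penalty."""
    if isinstance(material, MooneyRivlinParams):
        W = mooney_rivlin_energy(state, material)
    elif isinstance(material, HolzapfelParams):
        W = holzapfel_energy(state, material)
    else:
        raise TypeError(f"unknown material type {type(material).__name__}")
    if penalty is not None:
        W = W + 0.5 * penalty.kappa * (state.J - 1.0) ** 2
    return W


# ---------------------------------------------------------------------------
# per-region assignment
# ---------------------------------------------------------------------------

def default_material_table() -> dict:
    """Default per-tissue constants, kPa.

    Values are transcriptions from the arterial-plaque finite-element
    literature, rounded: Tang-style exponential Mooney-Rivlin constants for
    lipid (very soft) and calcification (~2 orders stiffer), and
    Holzapfel-type layer constants with the exponent moderated for the
    squared-(I1-3) isotropic coupling of the two-term form used here.  They
    are configuration data, not code: every run echoes its table into the
    manifest, and any entry may be overridden from the run config.
    """
    return {
        "lipid": {"model": "mooney_rivlin",
                  "parameters": {"c1": 2.0, "c2": 0.0, "d1": 2.0, "d2": 1.5},
                  "source": "soft lipid pool, Tang-style exponential MR constants"},
        "calcium": {"model": "mooney_rivlin",
                    "parameters": {"c1": 368.0, "c2": 0.0, "d1": 144.0, "d2": 2.0},
                    "source": "calcification ~100x lipid stiffness"},
        "fibrous": {"model": "holzapfel",
                    "parameters": {"mu": 14.0, "k1": 20.0, "k2": 15.0, "rho": 0.8},
                    "source": "fibrous intima, human coronary layer data (rounded)"},
        "media": {"model": "holzapfel",
                  "parameters": {"mu": 1.3, "k1": 21.6, "k2": 8.2, "rho": 0.85},
                  "source": "media, human coronary layer data (rounded)"},
        "adventitia": {"model": "holzapfel",
                       "parameters": {"mu": 3.8, "k1": 40.0, "k2": 30.0, "rho": 0.9},
                       "source": "adventitia, moderated strain-stiffening"},
    }


_MODEL_CLASSES = {"mooney_rivlin": MooneyRivlinParams, "holzapfel": HolzapfelParams}
_LAYER_TO_TISSUE = {
    "intima_fibrous": "fibrous", "intima_lipid": "lipid", "intima_calcium": "calcium",
    "fibrous": "fibrous", "lipid": "lipid", "calcium": "calcium",
    "media": "media", "adventitia": "adventitia",
}


def material_for_region(label: str, table: dict | None = None):
    """Resolve a region/tissue label to its material parameter object.

    Lipid and calcium are isotropic (Mooney-Rivlin); fibrous intima, media and
    adventitia are anisotropic (Holzapfel).  Accepts either tissue labels or
    the layered-geometry face labels (``intima_*`` prefixes).
    """
    if table is None:
        table = default_material_table()
    tissue = _LAYER_TO_TISSUE.get(label)
    if tissue is None:
        raise KeyError(f"unknown tissue label {label!r}")
    try:
        entry = table[tissue]
    except KeyError:
        raise KeyError(f"material table has no parameter set for {tissue!r}") from None
    model = entry["model"]
    expected = "mooney_rivlin" if tissue in ISOTROPIC_LABELS else "holzapfel"
    if model != expected:
        raise ValueError(f"{tissue!r} must use the {expected} model, table says {model!r}")
    return _MODEL_CLASSES[model](**entry["parameters"])
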