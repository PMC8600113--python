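"""Hyperelastic material models: energies, stresses, consistency."""

import numpy as np
import pytest

from plaquestress.materials import (HolzapfelParams, KinematicState,
                                    MooneyRivlinParams, VolumetricPenalty,
                                    cauchy_stress, default_material_table,
                                    holzapfel_energy, material_for_region,
                                    mooney_rivlin_energy, penalty_for,
                                    pk1_stress, total_energy)

MR = MooneyRivlinParams(c1=2.0, c2=0.5, d1=2.0, d2=1.5)
HO = HolzapfelParams(mu=14.0, k1=20.0, k2=15.0, rho=0.8)
PEN = VolumetricPenalty(500.0)
FIBER = np.array([1.0, 0.0])


def random_states(n, scale=0.12, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(2) + scale * rng.normal(size=(2, 2))
        if np.linalg.det(F) > 0.3:
            a = rng.normal(size=2)
            out.append((F, a / np.linalg.norm(a)))
    return out


class TestEnergies:
    def test_undeformed_reference_is_zero(self):
        st = KinematicState.identity()
        assert mooney_rivlin_energy(st, MR) == 0.0
        assert holzapfel_energy(st, HO) == 0.0
        assert np.all(cauchy_stress(st, HO, PEN) == 0.0)
        assert np.all(cauchy_stress(st, MR, PEN) == 0.0)

    def test_mooney_rivlin_reduces_without_exponential(self):
        p2 = MooneyRivlinParams(c1=3.0, c2=1.0, d1=0.0, d2=0.0)
        for F, a in random_states(20, seed=1):
            st = KinematicState(F, fiber=a)
            w = mooney_rivlin_energy(st, p2)
            assert w == pytest.approx(
                3.0 * (st.I1_bar - 3) + 1.0 * (st.I2_bar - 3), rel=1e-12)

    def test_mooney_rivlin_isochoric_stretch_closed_form(self):
        lam = 1.2
        F = np.diag([lam, 1 / lam])  # isochoric plane-strain stretch, J = 1
        st = KinematicState(F)
        i1 = lam ** 2 + lam ** -2 + 1.0
        i2 = lam ** 2 + lam ** -2 + 1.0  # for J=1 plane strain, I2 = I1
        expected = (MR.c1 * (i1 - 3) + MR.c2 * (i2 - 3)
                    + MR.d1 * (np.exp(MR.d2 * (i1 - 3)) - 1.0))
        assert mooney_rivlin_energy(st, MR) == pytest.approx(expected, rel=1e-10)

    def test_holzapfel_fiber_stretch_closed_form(self):
        lam = 1.1
        F = np.diag([lam, 1 / lam])
        st = KinematicState(F, fiber=FIBER)
        i1 = lam ** 2 + lam ** -2 + 1.0
        i4 = lam ** 2
        Q = (1 - HO.rho) * (i1 - 3) ** 2 + HO.rho * (i4 - 1) ** 2
        expected = HO.mu * (i1 - 3) + HO.k1 / HO.k2 * (np.exp(HO.k2 * Q) - 1)
        assert holzapfel_energy(st, HO) == pytest.approx(expected, rel=1e-10)

    def test_dispersion_limit_isotropic(self):
        iso = HolzapfelParams(mu=10.0, k1=5.0, k2=2.0, rho=0.0)
        for F, a in random_states(20, seed=2):
            w1 = holzapfel_energy(KinematicState(F, fiber=a), iso)
            w2 = holzapfel_energy(KinematicState(F, fiber=[0.0, 1.0]), iso)
            assert w1 == pytest.approx(w2, rel=1e-12)

    def test_neo_hookean_degeneracy(self):
        nh = HolzapfelParams(mu=10.0, k1=1e-12, k2=1.0, rho=0.0)
        for F, a in random_states(10, seed=3):
            st = KinematicState(F, fiber=a)
            assert holzapfel_energy(st, nh) == pytest.approx(
                10.0 * (st.I1_bar - 3), rel=1e-6)

    def test_fiber_compression_switch(self):
        lam = 0.9  # fiber shortened: tension-only term must vanish
        st = KinematicState(np.diag([lam, 1 / lam]), fiber=FIBER)
        p_active = HolzapfelParams(mu=1e-12, k1=10.0, k2=5.0, rho=1.0)
        assert holzapfel_energy(st, p_active) == pytest.approx(0.0, abs=1e-10)
        p_off = HolzapfelParams(mu=1e-12, k1=10.0, k2=5.0, rho=1.0,
                                tension_only=False)
        assert holzapfel_energy(st, p_off) > 0.0

    def test_exponential_overflow_reported(self):
        st = KinematicState(np.diag([4.0, 4.0]), fiber=FIBER)
        with pytest.raises(OverflowError, match="D2"):
            mooney_rivlin_energy(st, MooneyRivlinParams(1.0, 0.0, 1.0, 40.0))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HolzapfelParams(mu=1.0, k1=1.0, k2=-1.0, rho=0.5)
        with pytest.raises(ValueError):
            HolzapfelParams(mu=1.0, k1=1.0, k2=1.0, rho=1.5)
        with pytest.raises(ValueError):
            MooneyRivlinParams(0.0, 0.0, 0.0, 0.0)


class TestStress:
    @pytest.mark.parametrize("mat", [MR, HO], ids=["mooney_rivlin", "holzapfel"])
    def test_stress_matches_energy_derivative(self, mat):
        """PK1 from the implementation vs central FD of the total energy."""
        h = 1e-6
        for F, a in random_states(100, seed=4):
            st = KinematicState(F, fiber=a)
            P = pk1_stress(st, mat, PEN)[:2, :2]
            Pfd = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    Fp = F.copy(); Fp[i, j] += h
                    Fm = F.copy(); Fm[i, j] -= h
                    Pfd[i, j] = (total_energy(KinematicState(Fp, fiber=a), mat, PEN)
                                 - total_energy(KinematicState(Fm, fiber=a), mat, PEN)
                                 ) / (2 * h)
            scale = max(np.abs(Pfd).max(), 1e-9)
            assert np.abs(P - Pfd).max() / scale < 1e-6

    def test_small_perturbation_consistency(self):
        rng = np.random.default_rng(5)
        for eps in (1e-4, 1e-5):
            A = rng.normal(size=(2, 2))
            st = KinematicState(np.eye(2) + eps * A, fiber=FIBER)
            sig = cauchy_stress(st, HO, PEN)
            assert np.allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-12)
            assert np.abs(sig).max() < 50 * eps * max(PEN.kappa, 1.0)

    def test_objectivity_under_rotation(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            th = rng.uniform(0, 2 * np.pi)
            Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            F = np.eye(2) + 0.05 * rng.normal(size=(2, 2))
            if np.linalg.det(F) <= 0:
                continue
            for mat in (MR, HO):
                w1 = total_energy(KinematicState(F, fiber=FIBER), mat, PEN)
                w2 = total_energy(KinematicState(Q @ F, fiber=FIBER), mat, PEN)
                assert w2 == pytest.approx(w1, rel=1e-10)

    def test_nonpositive_jacobian_rejected(self):
        with pytest.raises(ValueError, match="det"):
            KinematicState(np.diag([1.0, -1.0]))


class TestAssignment:
    def test_isotropic_and_anisotropic_routing(self):
        assert isinstance(material_for_region("lipid"), MooneyRivlinParams)
        assert isinstance(material_for_region("calcium"), MooneyRivlinParams)
        for label in ("fibrous", "media", "adventitia", "intima_fibrous"):
            assert isinstance(material_for_region(label), HolzapfelParams)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="thrombus"):
            material_for_region("thrombus")

    def test_missing_parameter_set_names_label(self):
        table = {k: v for k, v in default_material_table().items() if k != "media"}
        with pytest.raises(KeyError, match="media"):
            material_for_region("media", table)

    def test_penalty_scale(self):
        pen = penalty_for(HolzapfelParams(mu=10.0, k1=5.0, k2=1.0, rho=0.5),
                          factor=1000.0)
        assert pen.kappa == pytest.approx(1000.0 * (2 * 10.0 + 5.0))
        assert pen.kappa >= 100 * (2 * 10.0 + 5.0)
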