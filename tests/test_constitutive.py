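"""Unit and property tests of the two-fiber-family wall model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aawall.constitutive as co
from aawall.constitutive import (
    MaterialParameters, DeformationState, fiber_directions, isochoric_invariants,
    strain_energy, cauchy_stress, material_tangent, ConstitutiveOverflow,
    REFERENT_NORMAL, BASELINE_AAA,
)


def _state(F, phi=45.0):
    a04, a06 = fiber_directions(phi)
    return DeformationState(F=np.asarray(F, float), a04=a04, a06=a06)


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _tensile_F(rng, scale=0.05):
    # random deformation biased to keep both fiber families in extension
    A = scale * rng.standard_normal((3, 3))
    F = np.eye(3) + A
    F[1, 1] += scale
    F[2, 2] += scale
    return F


class TestInvariants:
    def test_undeformed_state(self):
        I1, I4, I6 = isochoric_invariants(_state(np.eye(3)))
        assert np.allclose([I1, I4, I6], [3.0, 1.0, 1.0])

    def test_equibiaxial_in_plane_values(self):
        # diag(1/1.21, 1.1, 1.1) in (r, theta, z), phi = 45 deg, J = 1:
        # Ibar4 = Ibar6 = lam_theta^2 sin^2 + lam_z^2 cos^2 = 1.21
        F = np.diag([1 / 1.21, 1.1, 1.1])
        I1, I4, I6 = isochoric_invariants(_state(F, phi=45.0))
        assert I1 == pytest.approx(3.103013455, rel=1e-8)
        assert I4 == pytest.approx(1.21, rel=1e-12)
        assert I6 == pytest.approx(1.21, rel=1e-12)

    def test_objectivity_under_rotation(self):
        rng = np.random.default_rng(7)
        F = _tensile_F(rng)
        base = isochoric_invariants(_state(F))
        for _ in range(5):
            Q = _random_rotation(rng)
            rot = isochoric_invariants(_state(Q @ F))
            assert np.allclose(rot, base, atol=1e-12)

    def test_invalid_deformation_rejected(self):
        with pytest.raises(ValueError):
            isochoric_invariants(_state(-np.eye(3)))


class TestFiberDirections:
    @pytest.mark.parametrize("phi,a04", [
        (0.0, (0, 0, 1)),
        (90.0, (0, 1, 0)),
        (45.0, (0, np.sqrt(2) / 2, np.sqrt(2) / 2)),
    ])
    def test_helix_angles(self, phi, a04):
        v4, v6 = fiber_directions(phi)
        assert np.allclose(v4, a04, atol=1e-15)
        assert np.allclose(v6, [a04[0], -a04[1], a04[2]], atol=1e-15)
        assert np.linalg.norm(v4) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fiber_directions(91.0)


class TestStrainEnergy:
    def test_zero_at_reference(self):
        assert strain_energy(REFERENT_NORMAL, _state(np.eye(3), 36.0)) == pytest.approx(0.0)

    def test_no_fiber_energy_at_unit_fiber_stretch(self):
        # phi = 90: fibers circumferential; lam_theta = 1 keeps Ibar4 = Ibar6 = 1
        F = np.diag([1 / 1.3, 1.0, 1.3])
        p = MaterialParameters(mu=0.007, k1=2.87, k2=17.26, phi=90.0)
        psi = strain_energy(p, _state(F, 90.0))
        p0 = MaterialParameters(mu=0.007, k1=0.0, k2=17.26, phi=90.0)
        assert psi == pytest.approx(strain_energy(p0, _state(F, 90.0)), rel=1e-12)

    def test_isotropic_part_hand_value(self):
        # mu/2 (Ibar1 - 3) with Ibar1 = 3.103013 and mu = 0.007 -> 3.605e-4 MPa
        F = np.diag([1 / 1.21, 1.1, 1.1])
        p = MaterialParameters(mu=0.007, k1=0.0, k2=17.26, phi=36.0)
        psi = strain_energy(p, _state(F, 36.0))
        assert psi == pytest.approx(0.0035 * 0.103013455, rel=1e-8)

    def test_small_k2_series_limit(self):
        F = np.diag([1 / 1.21, 1.1, 1.1])
        p = MaterialParameters(mu=0.007, k1=2.0, k2=1e-12, phi=45.0)
        psi_fib = strain_energy(p, _state(F)) - strain_energy(
            MaterialParameters(mu=0.007, k1=0.0, k2=1e-12, phi=45.0), _state(F))
        # k2 -> 0: each family contributes k1/2 (Ibar-1)^2
        assert psi_fib == pytest.approx(2 * 0.5 * 2.0 * 0.21**2, rel=1e-6)

    def test_overflow_reported_not_clamped(self):
        p = MaterialParameters(mu=0.013, k1=2.74, k2=500.0, phi=45.0)
        F = np.diag([1 / 4.0, 2.0, 2.0])
        with pytest.raises(ConstitutiveOverflow):
            strain_energy(p, _state(F))

    def test_monotone_in_stretch(self):
        p = BASELINE_AAA
        vals = [strain_energy(p, _state(np.diag([1 / (s * s), s, s])))
                for s in (1.02, 1.05, 1.08, 1.12)]
        assert np.all(np.diff(vals) > 0)


class TestCauchyStress:
    def test_zero_at_reference(self):
        sig = cauchy_stress(BASELINE_AAA, _state(np.eye(3)))
        assert np.allclose(sig, 0.0, atol=1e-12)

    def test_matches_energy_gradient(self):
        """sigma = (1/J) (dpsi/dF) F^T by central finite differences."""
        rng = np.random.default_rng(3)
        for params in (REFERENT_NORMAL, BASELINE_AAA):
            a04, a06 = fiber_directions(params.phi)
            F = _tensile_F(rng)
            sig = cauchy_stress(params, DeformationState(F, a04, a06))
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for J in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, J] += h
                    Fm[i, J] -= h
                    P[i, J] = (strain_energy(params, DeformationState(Fp, a04, a06))
                               - strain_energy(params, DeformationState(Fm, a04, a06))) / (2 * h)
            sig_fd = P @ F.T / np.linalg.det(F)
            assert np.abs(sig - sig_fd).max() < 1e-5 * np.abs(sig).max()

    def test_neo_hookean_uniaxial_closed_form(self):
        mu, lam = 0.007, 1.3
        p = MaterialParameters(mu=mu, k1=0.0, k2=1.0, phi=0.0, kappa_vol=mu * 1e5)
        F = np.diag([lam**-0.5, lam**-0.5, lam])
        sig = cauchy_stress(p, _state(F, 0.0))
        assert sig[2, 2] - sig[0, 0] == pytest.approx(mu * (lam**2 - 1 / lam), rel=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_objectivity(self, seed):
        rng = np.random.default_rng(seed)
        F = _tensile_F(rng)
        Q = _random_rotation(rng)
        a04, a06 = fiber_directions(45.0)
        s1 = cauchy_stress(BASELINE_AAA, DeformationState(Q @ F, a04, a06))
        s2 = Q @ cauchy_stress(BASELINE_AAA, DeformationState(F, a04, a06)) @ Q.T
        assert np.abs(s1 - s2).max() < 1e-10 * max(np.abs(s2).max(), 1.0)

    def test_fiber_swap_symmetry(self):
        rng = np.random.default_rng(11)
        F = _tensile_F(rng)
        a04, a06 = fiber_directions(36.0)
        s1 = cauchy_stress(REFERENT_NORMAL, DeformationState(F, a04, a06))
        s2 = cauchy_stress(REFERENT_NORMAL, DeformationState(F, a06, a04))
        assert np.allclose(s1, s2, atol=1e-14)
        e1 = strain_energy(REFERENT_NORMAL, DeformationState(F, a04, a06))
        e2 = strain_energy(REFERENT_NORMAL, DeformationState(F, a06, a04))
        assert e1 == pytest.approx(e2, rel=1e-14)

    def test_mirrored_helix_angle_symmetry(self):
        # swapping the sign of phi exchanges the two families: energy invariant
        rng = np.random.default_rng(12)
        F = _tensile_F(rng)
        a04, a06 = fiber_directions(36.0)
        m04 = np.array([a04[0], -a04[1], a04[2]])
        m06 = np.array([a06[0], -a06[1], a06[2]])
        e1 = strain_energy(REFERENT_NORMAL, DeformationState(F, a04, a06))
        e2 = strain_energy(REFERENT_NORMAL, DeformationState(F, m04, m06))
        assert e1 == pytest.approx(e2, rel=1e-14)

    def test_energy_zero_iff_rotation(self):
        rng = np.random.default_rng(4)
        Q = _random_rotation(rng)
        assert strain_energy(BASELINE_AAA, _state(Q)) == pytest.approx(0.0, abs=1e-20)
        F = _tensile_F(rng)
        assert strain_energy(BASELINE_AAA, _state(F)) > 1e-8


class TestMaterialTangent:
    def test_matches_stress_finite_differences(self):
        """Spatial tangent reproduces FD of Cauchy stress (rel err < 1e-4).

        For a velocity-gradient perturbation F -> (1 + h u) F with symmetric
        u, the exact linearization is
        d sigma = c : u + u sigma + sigma u - sigma tr(u).
        """
        rng = np.random.default_rng(5)
        for params in (REFERENT_NORMAL, BASELINE_AAA):
            a04, a06 = fiber_directions(params.phi)
            F = _tensile_F(rng, scale=0.03)
            st = DeformationState(F, a04, a06)
            c = material_tangent(params, st)
            sig = cauchy_stress(params, st)
            h = 1e-6
            err = 0.0
            for k in range(3):
                for l in range(k, 3):
                    u = np.zeros((3, 3))
                    u[k, l] = u[l, k] = 1.0
                    d = h * u
                    sp = cauchy_stress(params, DeformationState((np.eye(3) + d) @ F, a04, a06))
                    sm = cauchy_stress(params, DeformationState((np.eye(3) - d) @ F, a04, a06))
                    fd = (sp - sm) / (2 * h)
                    pred = (np.einsum("ijkl,kl->ij", c, u)
                            + u @ sig + sig @ u - sig * np.trace(u))
                    err = max(err, np.abs(pred - fd).max())
            assert err < 1e-4 * np.abs(c).max()

    def test_consistent_with_pk2_derivative(self):
        """Reference tangent 2 dS/dC vs central FD of the analytic S (rel < 1e-4)."""
        rng = np.random.default_rng(6)
        params = REFERENT_NORMAL
        a04, a06 = fiber_directions(params.phi)
        F = _tensile_F(rng, scale=0.04)
        C = F.T @ F
        h = 1e-6
        worst_diff, scale = 0.0, 0.0
        for K in range(3):
            for L in range(K, 3):
                dC = np.zeros((3, 3))
                dC[K, L] += 0.5 * h
                dC[L, K] += 0.5 * h
                Sp = co.pk2_stress(params, C + dC, a04, a06)
                Sm = co.pk2_stress(params, C - dC, a04, a06)
                fd = (Sp - Sm) / (2 * h)    # dS along the symmetrized direction
                dCc = np.zeros((3, 3), complex)
                dCc[K, L] += 0.5j * co._CS_EPS
                dCc[L, K] += 0.5j * co._CS_EPS
                cs = co.pk2_stress(params, C.astype(complex) + dCc, a04, a06).imag / co._CS_EPS
                worst_diff = max(worst_diff, np.abs(cs - fd).max())
                scale = max(scale, np.abs(fd).max())
        assert worst_diff < 1e-4 * scale

    def test_minor_symmetries(self):
        rng = np.random.default_rng(8)
        params = BASELINE_AAA
        a04, a06 = fiber_directions(params.phi)
        c = material_tangent(params, DeformationState(_tensile_F(rng), a04, a06))
        assert np.abs(c - np.swapaxes(c, 0, 1)).max() < 1e-10 * np.abs(c).max()
        assert np.abs(c - np.swapaxes(c, 2, 3)).max() < 1e-10 * np.abs(c).max()

    def test_isotropic_limit_at_reference(self):
        """k1 = 0 at F = I: classical isochoric neo-Hookean + volumetric moduli."""
        mu, kap = 0.007, 10.0
        p = MaterialParameters(mu=mu, k1=0.0, k2=1.0, phi=0.0, kappa_vol=kap)
        a04, a06 = fiber_directions(0.0)
        c = material_tangent(p, DeformationState(np.eye(3), a04, a06))
        I = np.eye(3)
        Isym = 0.5 * (np.einsum("ik,jl->ijkl", I, I) + np.einsum("il,jk->ijkl", I, I))
        IxI = np.einsum("ij,kl->ijkl", I, I)
        expected = kap * IxI + 2 * mu * (Isym - IxI / 3.0)
        assert np.abs(c - expected).max() < 1e-8 * np.abs(expected).max()


class TestParameters:
    def test_default_volumetric_modulus(self):
        p = MaterialParameters(mu=0.013, k1=1.0, k2=1.0, phi=45.0)
        assert p.kappa_vol == pytest.approx(13.0)
        p2 = MaterialParameters(mu=0.001, k1=1.0, k2=1.0, phi=45.0)
        assert p2.kappa_vol == pytest.approx(10.0)  # floor at 1000 * 0.01

    @pytest.mark.parametrize("kw", [
        {"mu": -1.0}, {"k1": -1.0}, {"k2": -0.5}, {"phi": 95.0},
        {"kappa_vol": 0.1},
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = {"mu": 0.013, "k1": 2.74, "k2": 119.6, "phi": 45.0}
        base.update(kw)
        with pytest.raises(ValueError):
            MaterialParameters(**base)

    def test_presets_match_reported_tissue_values(self):
        assert (REFERENT_NORMAL.mu, REFERENT_NORMAL.k1, REFERENT_NORMAL.k2,
                REFERENT_NORMAL.phi) == (0.007, 2.87, 17.26, 36.0)
        assert (BASELINE_AAA.mu, BASELINE_AAA.k1, BASELINE_AAA.k2,
                BASELINE_AAA.phi) == (0.013, 2.74, 119.6, 45.0)


class TestConfigLoading:
    def test_presets_by_name(self):
        assert co.load_material("referent_normal") is REFERENT_NORMAL
        assert co.load_material("baseline_aaa") is BASELINE_AAA

    def test_yaml_key_value_config(self, tmp_path):
        cfg = tmp_path / "mat.yaml"
        cfg.write_text("mu: 0.013\nk1: 2.74\nk2: 119.6\nphi: 45.0\n"
                       "kappa_vol: 13.0\nfiber_tension_only: false\n")
        p = co.load_material(cfg)
        assert (p.mu, p.k1, p.k2, p.phi) == (0.013, 2.74, 119.6, 45.0)
        assert p.kappa_vol == 13.0 and p.fiber_tension_only is False

    def test_unknown_keys_rejected(self, tmp_path):
        cfg = tmp_path / "mat.yaml"
        cfg.write_text("mu: 0.013\nk1: 2.74\nk2: 119.6\nphi: 45.0\ndispersion: 0.2\n")
        with pytest.raises(ValueError):
            co.load_material(cfg)
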