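"""Unit tests for the constitutive module: stiffness and growth laws,
neo-Hookean stress/energy/tangent, and the irreversibility ratchet."""

import numpy as np
import pytest

from cortigrow.constitutive import (
    GrowthState,
    MaterialParams,
    cauchy_stress,
    cortical_shear_modulus,
    elastic_moduli,
    elastic_part,
    first_piola_elastic,
    growth_factors,
    growth_multipliers,
    growth_tensor,
    lame_lambda,
    shear_modulus_profile,
    smooth_heaviside,
    strain_energy,
    update_growth_state,
)


class TestSmoothHeaviside:
    def test_midpoint(self):
        assert smooth_heaviside(0.0, 20.0) == pytest.approx(0.5)

    def test_value(self):
        # e^2 / (1 + e^2)
        assert smooth_heaviside(0.1, 20.0) == pytest.approx(0.8807970779778823)

    def test_complement(self):
        x = np.linspace(-3, 3, 41)
        np.testing.assert_allclose(
            smooth_heaviside(x, 20.0) + smooth_heaviside(-x, 20.0), 1.0
        )

    def test_overflow_safe(self):
        assert smooth_heaviside(1e4, 50.0) == pytest.approx(1.0)
        assert smooth_heaviside(-1e4, 50.0) == pytest.approx(0.0)

    def test_monotone(self):
        x = np.linspace(-2, 2, 201)
        assert np.all(np.diff(smooth_heaviside(x, 10.0)) > 0)


class TestMaterialParams:
    def test_derived_slope_and_substrate(self):
        p = MaterialParams()  # varying, beta_mu = 3
        assert p.mu_s == pytest.approx(0.69)
        assert p.m_c == pytest.approx((2.07 - 0.69) / 500.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"mu_inf": -1.0},
            {"poisson_nu": 0.5},
            {"poisson_nu": 0.0},
            {"beta_mu": 0.5},
            {"c_max": 100.0, "c_min": 200.0},
            {"kappa_s": -1e-4},
            {"alpha": 0.0},
            {"beta_kappa": 0.5},
            {"stiffness_mode": "magic"},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            MaterialParams(**kw)


class TestStiffness:
    def test_ramp_endpoints(self):
        p = MaterialParams(stiffness_mode="varying", beta_mu=3.0)
        assert cortical_shear_modulus(200.0, p) == pytest.approx(0.69)
        assert cortical_shear_modulus(700.0, p) == pytest.approx(2.07)
        assert cortical_shear_modulus(450.0, p) == pytest.approx(1.38)

    def test_clamped_outside_ramp(self):
        p = MaterialParams()
        assert cortical_shear_modulus(0.0, p) == pytest.approx(p.mu_s)
        assert cortical_shear_modulus(5000.0, p) == pytest.approx(p.mu_inf)

    def test_constant_mode(self):
        p = MaterialParams(stiffness_mode="constant", beta_mu=8.0)
        np.testing.assert_allclose(
            cortical_shear_modulus(np.array([0.0, 450.0, 900.0]), p), 2.07
        )

    def test_profile_blends_at_cortex(self):
        p = MaterialParams()
        mid = shear_modulus_profile(1.8, 700.0, p)
        assert mid == pytest.approx(p.mu_s + 0.5 * (p.mu_inf - p.mu_s))
        assert shear_modulus_profile(0.5, 700.0, p) == pytest.approx(p.mu_s, rel=1e-6)
        assert shear_modulus_profile(2.5, 700.0, p) == pytest.approx(p.mu_inf, rel=1e-4)

    def test_stiffness_bounds_both_modes(self):
        ri = np.linspace(0.4, 2.0, 50)
        c = np.linspace(0.0, 900.0, 50)
        for mode, bm in (("varying", 3.0), ("constant", 8.0)):
            p = MaterialParams(stiffness_mode=mode, beta_mu=bm)
            mu = shear_modulus_profile(ri[:, None], c[None, :], p)
            assert np.all(mu >= p.mu_s - 1e-12)
            assert np.all(mu <= p.mu_inf + 1e-12)


class TestLame:
    def test_value(self):
        assert lame_lambda(0.69, 0.38) == pytest.approx(2.0 * 0.69 * 0.38 / 0.24)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            lame_lambda(1.0, 0.5)


class TestGrowthLaw:
    def test_subcortex_isotropic(self):
        p = MaterialParams()
        kp, kl = growth_factors(0.5, p)
        assert kp == pytest.approx(p.kappa_s, rel=1e-6)
        assert kl == pytest.approx(p.kappa_s, rel=1e-6)

    def test_cortex_limit(self):
        p = MaterialParams(beta_kappa=3.0)
        kp, kl = growth_factors(100.0, p)
        assert kp == pytest.approx(3.0 * p.kappa_s)
        assert kl == pytest.approx(p.kappa_s / 3.0)

    def test_transition_midpoint(self):
        p = MaterialParams(beta_kappa=3.0)
        kp, _ = growth_factors(1.8, p)
        assert kp == pytest.approx(p.kappa_s * (1.0 + (3.0 - 1.0) / 2.0))

    def test_multipliers_at_zero_density(self):
        tp, tl = growth_multipliers(0.0, 1e-3, 1e-4, 1.65)
        assert tp == pytest.approx(1.0)
        assert tl == pytest.approx(1.0)

    def test_multiplier_value(self):
        # (1 + 4.07e-4 * 500)^1.65
        tp, _ = growth_multipliers(500.0, 4.07e-4, 4.07e-4, 1.65)
        assert tp == pytest.approx((1.0 + 4.07e-4 * 500.0) ** 1.65)

    def test_multipliers_increase_with_density(self):
        c = np.linspace(0.0, 900.0, 40)
        tp, tl = growth_multipliers(c, 1e-3, 1e-4, 1.65)
        assert np.all(np.diff(tp) > 0)
        assert np.all(np.diff(tl) > 0)

    def test_cortical_anisotropy(self):
        # in the cortex limit theta_perp > theta_par for any c > 0
        p = MaterialParams(beta_kappa=3.0)
        kp, kl = growth_factors(100.0, p)
        c = np.array([1.0, 100.0, 700.0])
        tp, tl = growth_multipliers(c, kp, kl, p.alpha)
        assert np.all(tp > tl)

    def test_subcortical_spherical_growth(self):
        p = MaterialParams()
        ri = np.linspace(0.4, 1.0, 20)
        kp, kl = growth_factors(ri, p)
        assert np.all(np.abs(kp - kl) / p.kappa_s < 1e-4)


class TestGrowthTensor:
    def test_structure(self):
        Fg = growth_tensor(1.05, 1.2, np.array([0.0, 1.0]))
        np.testing.assert_allclose(Fg, [[1.05, 0.0], [0.0, 1.2]])

    def test_determinant(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tp, tl = rng.uniform(1.0, 1.5, 2)
            th = rng.uniform(0, 2 * np.pi)
            N = np.array([np.cos(th), np.sin(th)])
            assert np.linalg.det(growth_tensor(tp, tl, N)) == pytest.approx(tp * tl)

    def test_eigen_relation(self):
        N = np.array([3.0, 4.0]) / 5.0
        Fg = growth_tensor(1.1, 1.4, N)
        np.testing.assert_allclose(Fg @ N, 1.4 * N)

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ValueError):
            growth_tensor(1.0, 1.0, np.array([1.0, 1.0]))


class TestKinematics:
    def test_multiplicative_split(self):
        rng = np.random.default_rng(1)
        F = np.eye(2) + 0.1 * rng.standard_normal((5, 2, 2))
        Fg = growth_tensor(
            np.full(5, 1.2), np.full(5, 1.05), np.array([1.0, 0.0])
        )
        Fe = elastic_part(F, Fg)
        np.testing.assert_allclose(Fe @ Fg, F, atol=1e-13)

    def test_pure_growth_is_stress_free(self):
        Fg = growth_tensor(1.3, 1.1, np.array([0.0, 1.0]))
        Fe = elastic_part(Fg, Fg)
        np.testing.assert_allclose(Fe, np.eye(2), atol=1e-14)

    def test_negative_growth_det_rejected(self):
        with pytest.raises(ValueError):
            elastic_part(np.eye(2), np.diag([1.0, -1.0]))


class TestStress:
    def test_zero_at_identity(self):
        sig = cauchy_stress(np.eye(2), 1.0, 2.0)
        assert np.all(sig == 0.0)
        sig3 = cauchy_stress(np.eye(3), 1.0, 2.0)
        assert np.all(sig3 == 0.0)

    def test_energy_zero_at_identity(self):
        assert strain_energy(np.eye(2), 1.0, 2.0) == 0.0
        assert strain_energy(np.eye(3), 1.0, 2.0) == 0.0

    def test_plane_strain_embedding(self):
        # a 2x2 state and its 3x3 plane-strain embedding agree
        Fe2 = np.array([[1.1, 0.05], [0.0, 0.93]])
        Fe3 = np.eye(3)
        Fe3[:2, :2] = Fe2
        mu, lam = 0.8, 1.9
        assert strain_energy(Fe2, mu, lam) == pytest.approx(
            strain_energy(Fe3, mu, lam)
        )
        np.testing.assert_allclose(
            cauchy_stress(Fe2, mu, lam), cauchy_stress(Fe3, mu, lam)[:2, :2]
        )

    def test_energy_nonnegative_near_identity(self):
        rng = np.random.default_rng(2)
        Fe = np.eye(2) + 0.15 * rng.standard_normal((200, 2, 2))
        Fe = Fe[np.linalg.det(Fe) > 0.2]
        psi = strain_energy(Fe, 1.0, 2.0)
        assert np.all(psi >= -1e-12)

    def test_stress_matches_energy_gradient(self):
        # first Piola from a central finite difference of the energy
        rng = np.random.default_rng(3)
        mu, lam = 0.69, 2.185
        h = 1e-6
        for _ in range(100):
            Fe = np.eye(2) + rng.uniform(-0.2, 0.2, (2, 2))
            if np.linalg.det(Fe) < 0.3:
                continue
            P = first_piola_elastic(Fe, mu, lam)
            Pfd = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    dp = Fe.copy()
                    dm = Fe.copy()
                    dp[i, j] += h
                    dm[i, j] -= h
                    Pfd[i, j] = (
                        strain_energy(dp, mu, lam) - strain_energy(dm, mu, lam)
                    ) / (2 * h)
            assert np.linalg.norm(P - Pfd) / np.linalg.norm(P) < 1e-5
            # Cauchy from Piola: sigma = (1/Je) P Fe^T
            sig = cauchy_stress(Fe, mu, lam)
            sig_from_P = P @ Fe.T / np.linalg.det(Fe)
            np.testing.assert_allclose(sig, sig_from_P, atol=1e-10)

    def test_objectivity(self):
        rng = np.random.default_rng(4)
        mu, lam = 1.0, 2.0
        for _ in range(20):
            Fe = np.eye(2) + rng.uniform(-0.2, 0.2, (2, 2))
            if np.linalg.det(Fe) < 0.3:
                continue
            a = rng.uniform(0, 2 * np.pi)
            Q = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            np.testing.assert_allclose(
                cauchy_stress(Q @ Fe, mu, lam),
                Q @ cauchy_stress(Fe, mu, lam) @ Q.T,
                atol=1e-12,
            )

    def test_stress_symmetric(self):
        rng = np.random.default_rng(5)
        Fe = np.eye(2) + 0.2 * rng.standard_normal((50, 2, 2))
        Fe = Fe[np.linalg.det(Fe) > 0.3]
        sig = cauchy_stress(Fe, 1.0, 2.0)
        np.testing.assert_allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-13)

    def test_inverted_state_rejected(self):
        bad = np.diag([1.0, -1.0])
        for fn in (strain_energy, first_piola_elastic, cauchy_stress):
            with pytest.raises(ValueError):
                fn(bad, 1.0, 2.0)


class TestTangent:
    def test_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        mu, lam = 0.69, 2.185
        h = 1e-6
        for _ in range(10):
            Fe = np.eye(2) + rng.uniform(-0.15, 0.15, (2, 2))
            A = elastic_moduli(Fe, np.float64(mu), np.float64(lam))
            for k in range(2):
                for L in range(2):
                    dp = Fe.copy()
                    dm = Fe.copy()
                    dp[k, L] += h
                    dm[k, L] -= h
                    Afd = (
                        first_piola_elastic(dp, mu, lam)
                        - first_piola_elastic(dm, mu, lam)
                    ) / (2 * h)
                    np.testing.assert_allclose(
                        A[:, :, k, L], Afd, rtol=1e-4, atol=1e-7
                    )

    def test_major_symmetry(self):
        Fe = np.array([[1.08, 0.03], [-0.02, 0.94]])
        A = elastic_moduli(Fe, np.float64(1.0), np.float64(2.0))
        np.testing.assert_allclose(A, np.transpose(A, (2, 3, 0, 1)), atol=1e-13)


class TestRatchet:
    def test_componentwise_max(self):
        prev = GrowthState(np.array([1.2, 1.0]), np.array([1.0, 1.3]))
        prop = GrowthState(np.array([1.1, 1.4]), np.array([1.2, 1.1]))
        out = update_growth_state(prev, prop)
        np.testing.assert_allclose(out.theta_perp, [1.2, 1.4])
        np.testing.assert_allclose(out.theta_par, [1.2, 1.3])

    def test_never_decreases(self):
        rng = np.random.default_rng(7)
        state = GrowthState(np.ones(20), np.ones(20))
        for _ in range(30):
            prop = GrowthState(
                rng.uniform(0.8, 1.5, 20), rng.uniform(0.8, 1.5, 20)
            )
            new = update_growth_state(state, prop)
            assert np.all(new.theta_perp >= state.theta_perp)
            assert np.all(new.theta_par >= state.theta_par)
            state = new

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update_growth_state(
                GrowthState(np.ones(3), np.ones(3)),
                GrowthState(np.ones(4), np.ones(4)),
            )
        with pytest.raises(ValueError):
            GrowthState(np.ones(3), np.ones(4))
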