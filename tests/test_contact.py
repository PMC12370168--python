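import math

import numpy as np
import pytest

from nanorheo.contact import (
    GAMMA_MAX,
    GammaDomainError,
    NoRetractionError,
    PLRMaterial,
    ProbeCellGeometry,
    ValidityError,
    bec_terms,
    dimensionless_force,
    recover_modulus,
    relaxation_modulus,
    retraction_contact_time,
    simulate_force_curve,
)
from nanorheo.profiles import make_capped_sinusoid, make_triangular, random_profile

from oracle_utils import oracle_dimensionless_force, triangle_t1_closed_form


class TestRelaxationModulus:
    def test_reference_time_value(self):
        # psi(t0) = E0 / Gamma(1 - gamma); frozen value of 1/Gamma(0.7)
        mat = PLRMaterial(E0=1000.0, gamma=0.3)
        assert relaxation_modulus(1.0, mat) == pytest.approx(
            1000.0 / 1.2980553326475577, rel=1e-12
        )

    def test_elastic_material_is_time_independent(self):
        mat = PLRMaterial(E0=500.0, gamma=0.0)
        t = np.array([0.01, 0.1, 1.0, 10.0])
        assert np.allclose(relaxation_modulus(t, mat), 500.0)

    def test_power_law_decay(self):
        mat = PLRMaterial(E0=1000.0, gamma=0.5)
        assert relaxation_modulus(4.0, mat) == pytest.approx(
            relaxation_modulus(1.0, mat) / 2.0, rel=1e-12
        )

    def test_gamma_domain(self):
        with pytest.raises(GammaDomainError):
            PLRMaterial(E0=1000.0, gamma=1.0)
        with pytest.raises(GammaDomainError):
            PLRMaterial(E0=1000.0, gamma=-0.1)


class TestBottomEffectTerms:
    def test_semi_infinite_single_term(self, geometry_thick):
        terms = bec_terms(geometry_thick)
        assert len(terms) == 1
        alpha0, beta0 = terms[0]
        assert beta0 == 2.0
        assert alpha0 == pytest.approx(
            (2.0 / math.pi) * math.tan(geometry_thick.theta)
        )

    def test_thin_sample_terms_grow_with_order(self, geometry_thin):
        terms = bec_terms(geometry_thin)
        assert [beta for _, beta in terms] == [2.0, 3.0, 4.0]
        assert all(alpha > 0 for alpha, _ in terms)

    def test_validity_bound(self, geometry_thin):
        big = geometry_thin.h / math.tan(geometry_thin.theta) * 1.5
        prof = make_triangular(big, 10e-6, 10e-6)
        with pytest.raises(ValidityError):
            dimensionless_force(prof, 0.3, geometry_thin)


class TestElasticLimit:
    def test_matches_closed_form_polynomial(self, profile_zoo, geometry_thin):
        # gamma = 0: F(t) = E0 sum_j alpha_j (I(t)^(2+j) - I(0)^(2+j)); the
        # hereditary integral measures force relative to the initial state,
        # so a profile entering at a small eps > 0 subtracts its I(0) term
        for prof in profile_zoo:
            mat = PLRMaterial(E0=3000.0, gamma=0.0)
            curve = simulate_force_curve(prof, mat, geometry_thin, 301)
            terms = bec_terms(geometry_thin)
            poly = sum(alpha * curve.I**beta for alpha, beta in terms)
            poly0 = sum(alpha * curve.I[0] ** beta for alpha, beta in terms)
            # once I(t) falls below I(0) the contact is lost and F stays 0
            expected = mat.E0 * np.clip(poly - poly0, 0.0, None)
            scale = np.max(np.abs(expected))
            assert np.max(np.abs(curve.F - expected)) < 1e-9 * scale

    def test_zero_hysteresis(self, triangle, geometry_thick):
        curve = simulate_force_curve(
            triangle, PLRMaterial(E0=1000.0, gamma=0.0), geometry_thick, 401
        )
        area = np.trapezoid(curve.F, curve.I)
        assert abs(area) < 1e-6 * np.max(curve.F) * curve.I_max


class TestContactTime:
    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 0.75])
    def test_triangle_closed_form(self, triangle, gamma):
        t_max, t_tot = triangle.t_max, triangle.t_tot
        t = np.linspace(t_max, t_tot, 40)
        expected = triangle_t1_closed_form(t, t_max, gamma)
        keep = expected > 0  # after contact loss the formula goes negative
        t1 = retraction_contact_time(triangle, gamma, t)
        assert np.max(np.abs(t1[keep] - expected[keep])) < 1e-6 * t_tot
        assert np.all(t1[~keep] <= 1e-6 * t_tot)

    def test_boundary_and_monotonicity(self, triangle):
        t_max, t_tot = triangle.t_max, triangle.t_tot
        t = np.linspace(t_max, t_tot, 50)
        t1 = retraction_contact_time(triangle, 0.4, t)
        assert t1[0] == pytest.approx(t_max, abs=1e-9 * t_tot)
        assert np.all(np.diff(t1) <= 1e-12)

    def test_elastic_symmetry(self, triangle):
        # equal speeds, gamma = 0: t1 = 2 t_max - t
        t = np.linspace(triangle.t_max, triangle.t_tot, 20)
        t1 = retraction_contact_time(triangle, 0.0, t)
        assert np.allclose(t1, 2 * triangle.t_max - t, atol=1e-9 * triangle.t_tot)

    def test_requires_retraction_window(self, triangle):
        with pytest.raises(ValueError):
            retraction_contact_time(triangle, 0.3, 0.5 * triangle.t_max)


class TestScalingLaws:
    @pytest.mark.parametrize("k", [2.0, 10.0])
    @pytest.mark.parametrize("gamma", [0.2, 0.6])
    def test_time_compression_scales_force_by_k_gamma(
        self, geometry_thin, k, gamma
    ):
        mat = PLRMaterial(E0=2000.0, gamma=gamma)
        slow = make_triangular(1e-6, 2e-6, 2e-6)
        fast = make_triangular(1e-6, 2e-6 * k, 2e-6 * k)
        c_slow = simulate_force_curve(slow, mat, geometry_thin, 301)
        c_fast = simulate_force_curve(fast, mat, geometry_thin, 301)
        keep = c_slow.F > 1e-6 * c_slow.F.max()  # exclude t=0 and lost contact
        ratio = c_fast.F[keep] / c_slow.F[keep]
        assert np.allclose(ratio, k**gamma, rtol=1e-4)

    def test_linear_in_E0(self, triangle, geometry_thin):
        a = simulate_force_curve(
            triangle, PLRMaterial(E0=1000.0, gamma=0.35), geometry_thin, 201
        )
        b = simulate_force_curve(
            triangle, PLRMaterial(E0=7000.0, gamma=0.35), geometry_thin, 201
        )
        assert np.allclose(b.F, 7.0 * a.F, rtol=1e-12)

    def test_hysteresis_area_increases_with_gamma(self, triangle, geometry_thick):
        areas = []
        for gamma in (0.0, 0.2, 0.4, 0.6, 0.8):
            c = simulate_force_curve(
                triangle, PLRMaterial(E0=1000.0, gamma=gamma), geometry_thick, 301
            )
            areas.append(-np.trapezoid(c.I, c.F))  # loop area, positive
        assert all(b > a - 1e-15 for a, b in zip(areas, areas[1:]))
        assert areas[-1] > areas[0]

    def test_retraction_below_approach(self, geometry_thin):
        # representative soft-cell parameters: 5 kPa, gamma 0.3, h 7 um, 10 um/s
        prof = make_triangular(1e-6, 10e-6, 10e-6)
        c = simulate_force_curve(
            prof, PLRMaterial(E0=5000.0, gamma=0.3), geometry_thin, 401
        )
        mid = np.argmax(c.I)
        grid = np.linspace(0.1, 0.9, 30) * c.I_max
        f_app = np.interp(grid, c.I[: mid + 1], c.F[: mid + 1])
        f_ret = np.interp(grid, c.I[:mid:-1], c.F[:mid:-1])
        assert np.all(f_ret < f_app)
        assert -np.trapezoid(c.I, c.F) > 0


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_recover_modulus_inverts_simulation(self, seed, basis):
        rng = np.random.default_rng(seed)
        E0 = 10 ** rng.uniform(2, 5)
        gamma = rng.uniform(0.0, GAMMA_MAX)
        I_max = rng.uniform(0.3e-6, 3.5e-6)
        rho = rng.uniform(0.01, 1.0)
        theta = math.radians(25.0)
        geom = ProbeCellGeometry(theta=theta, h=math.tan(theta) * I_max / rho)
        kind = seed % 3
        if kind == 0:
            prof = make_triangular(I_max, 10e-6, rng.uniform(5e-6, 20e-6))
        elif kind == 1:
            prof = make_capped_sinusoid(I_max, rng.uniform(0.2, 2.0))
        else:
            prof = random_profile(seed + 100, basis, I_max=I_max,
                                  t_tot=rng.uniform(0.1, 2.0))
        curve = simulate_force_curve(
            prof, PLRMaterial(E0=E0, gamma=gamma), geom, 301
        )
        E0_hat = recover_modulus(
            curve.F_bar, curve.meta["f_bar"], gamma, curve.t_tot,
            curve.I_max, curve.v_bar, theta,
        )
        assert E0_hat == pytest.approx(E0, rel=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(4))
    def test_fast_solver_matches_adaptive_quadrature(
        self, trial, basis, geometry_thin
    ):
        # quick 4-profile version; the full 20-profile sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(trial)
        kind = trial % 3
        if kind == 0:
            prof = make_triangular(3.5e-6, 10e-6, rng.uniform(5e-6, 20e-6))
        elif kind == 1:
            prof = make_capped_sinusoid(3.5e-6, 0.7)
        else:
            prof = random_profile(int(rng.integers(1e6)), basis,
                                  I_max=3.5e-6, t_tot=0.5)
        gamma = rng.uniform(0.05, 0.9)
        rho = geometry_thin.rmax_over_h(prof.I_max)
        s_eval = np.array(
            [0.15, 0.35, prof.p * 0.999, min(prof.p + 0.08, 0.97), 0.85, 0.96]
        )
        ref = oracle_dimensionless_force(
            prof, gamma, rho, geometry_thin.a_coeffs, s_eval
        )
        df = dimensionless_force(prof, gamma, geometry_thin, n_points=1001)
        rel = np.max(np.abs(df(s_eval) - ref)) / np.max(np.abs(ref))
        assert rel < 1e-4


class TestErrorPaths:
    def test_gamma_out_of_domain(self, triangle, geometry_thick):
        with pytest.raises(GammaDomainError):
            dimensionless_force(triangle, 1.0, geometry_thick)

    def test_no_retraction_profile(self, basis):
        import dataclasses

        prof = make_triangular(1e-6, 1e-6, 1e-6, basis)
        approach_only = dataclasses.replace(prof, p=1.0 - 1e-12)
        with pytest.raises(NoRetractionError):
            retraction_contact_time(approach_only, 0.3, prof.t_tot)

    def test_force_zero_at_start_and_after_contact_loss(self, geometry_thick):
        # strong asymmetry: slow approach, fast retract -> early contact loss
        prof = make_triangular(1e-6, 1e-6, 50e-6)
        c = simulate_force_curve(
            prof, PLRMaterial(E0=1000.0, gamma=0.8), geometry_thick, 801
        )
        assert c.F[0] == 0.0
        # the last samples of the cycle carry no force once contact is lost
        tail = c.F[c.t > c.t_max + 0.8 * (c.t_tot - c.t_max)]
        assert np.allclose(tail, 0.0, atol=1e-12 * np.max(c.F))
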