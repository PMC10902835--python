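"""IGFT and AFT: variance interpolation, bubble branch, n* and δ fitting."""

import math

import numpy as np
import pytest
import sympy

from cavityfluc import constants
from cavityfluc.theory import (
    TheoryInputs,
    bubble_geometry,
    chi_igft,
    corrected_surface_tension,
    delta_r_increment,
    fit_delta,
    gaussian_model,
    mean_occupancy,
    mu0_aft,
    mu0_igft,
    mu_n_aft,
    mu_n_bubble,
    mu_n_gaussian,
    n_star_numeric,
    n_star_series,
    removal_work_bubble,
    removal_work_gaussian,
)


def _chi_reference(R, inputs):
    """Second, independently coded evaluation of the χ interpolation."""
    chi_inf = (
        inputs.rho
        * constants.KB_KJ_PER_MOL_K
        * inputs.temperature
        * inputs.kappa_T
        / constants.ATM_TO_KJ_PER_MOL_A3
    )
    eta = math.pi * inputs.rho * inputs.d_ww**3 / 6.0
    if 2 * R <= inputs.d_ww:
        return 1.0 - inputs.rho * 4.0 * math.pi * R**3 / 3.0
    u = inputs.d_ww / (2.0 * R)
    s = 1.0 - eta - chi_inf
    return chi_inf + (2 * s - 3 * eta) * u + (3 * eta - s) * u**2


class TestChi:
    def test_macroscopic_limit(self, ambient):
        # the deficit χ − χ∞ carries the 1/R surface correction, so the
        # approach to the compressibility limit is first order in d_ww/2R
        assert chi_igft(1e4, ambient) == pytest.approx(ambient.chi_inf, rel=1e-3)
        assert chi_igft(1e7, ambient) == pytest.approx(ambient.chi_inf, rel=1e-6)

    def test_small_R_limit_against_symbolic_evaluation(self, ambient):
        """Sub-diameter branch evaluated symbolically with sympy at R = 1e-6 Å."""
        R = sympy.Rational(1, 10**6)
        rho = sympy.Float(ambient.rho, 30)
        expected = 1 - rho * 4 * sympy.pi * R**3 / 3
        assert chi_igft(1e-6, ambient) == pytest.approx(float(expected), rel=1e-12)
        assert chi_igft(1e-6, ambient) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("R", [2.1, 3.7, 6.3])
    def test_double_implementation(self, R, ambient):
        assert chi_igft(R, ambient) == pytest.approx(
            _chi_reference(R, ambient), rel=1e-12
        )

    def test_continuity_at_solvent_diameter(self, ambient):
        half = ambient.d_ww / 2.0
        assert chi_igft(half * (1 - 1e-9), ambient) == pytest.approx(
            chi_igft(half * (1 + 1e-9), ambient), rel=1e-6
        )

    def test_monotone_decrease_toward_macroscopic(self, ambient):
        radii = np.linspace(1.4, 50.0, 200)
        chis = [chi_igft(R, ambient) for R in radii]
        assert all(a > b for a, b in zip(chis, chis[1:]))
        assert all(c > ambient.chi_inf for c in chis)


class TestGaussianBranch:
    def test_minimum_value_at_mean(self, ambient):
        R = 3.3
        m = gaussian_model(R, ambient)
        assert mu_n_gaussian(m.mean, R, ambient) == pytest.approx(
            0.5 * math.log(2 * math.pi * m.sigma2)
        )

    def test_symmetry_about_mean(self, ambient):
        R = 4.3
        m = gaussian_model(R, ambient)
        for x in (0.5, 2.0, 5.0):
            assert mu_n_gaussian(m.mean + x, R, ambient) == pytest.approx(
                mu_n_gaussian(m.mean - x, R, ambient)
            )

    def test_mu0_against_gaussian_density_oracle(self, ambient):
        """βμ0 equals −ln of the normalized Gaussian density at n = 0."""
        from scipy.stats import norm

        R = 2.9
        m = gaussian_model(R, ambient)
        oracle = -norm.logpdf(0.0, loc=m.mean, scale=math.sqrt(m.sigma2))
        assert mu0_igft(R, ambient) == pytest.approx(float(oracle), rel=1e-12)
        assert mu0_igft(R, ambient) == pytest.approx(
            float(mu_n_gaussian(0.0, R, ambient)), rel=1e-12
        )


class TestBubbleBranch:
    def test_full_cavity_has_no_bubble(self, ambient):
        R = 5.3
        st = bubble_geometry(mean_occupancy(R, ambient), R, ambient)
        assert st.V_bubble == pytest.approx(0.0, abs=1e-12)
        assert st.R_bubble == pytest.approx(0.0, abs=1e-6)

    def test_empty_cavity_bubble_fills_it(self, ambient):
        R = 5.3
        st = bubble_geometry(0.0, R, ambient)
        assert st.R_bubble == pytest.approx(R, rel=1e-12)

    def test_overfilled_cavity_rejected(self, ambient):
        with pytest.raises(ValueError):
            bubble_geometry(mean_occupancy(3.3, ambient) + 1.0, 3.3, ambient)

    def test_radial_increment_matches_reported_value(self, ambient):
        # δ = 0.83 at the mW ambient density corresponds to ΔR = 1.6 Å
        assert delta_r_increment(ambient) == pytest.approx(1.6, abs=0.05)

    def test_zero_tension_zero_pressure_reduces_to_constant(self):
        ti = TheoryInputs(pressure=0.0, gamma=0.0, delta=0.0)
        for n in (0.0, 5.0, 20.0):
            assert mu_n_bubble(n, 5.3, ti, epsilon_continuity=1.25) == pytest.approx(
                1.25
            )

    def test_removal_work_matches_finite_difference(self, ambient):
        """−dβμ_n/dn from the analytic form vs central differences."""
        R = 6.3
        h = 1e-4
        for n in (2.0, 10.0, 20.0):
            fd = -(
                mu_n_bubble(n + h, R, ambient) - mu_n_bubble(n - h, R, ambient)
            ) / (2 * h)
            assert removal_work_bubble(n, R, ambient) == pytest.approx(fd, abs=1e-6)
        hg = 1e-5
        for n in (5.0, 30.0):
            fd = -(
                mu_n_gaussian(n + hg, R, ambient) - mu_n_gaussian(n - hg, R, ambient)
            ) / (2 * hg)
            assert removal_work_gaussian(n, R, ambient) == pytest.approx(fd, abs=1e-6)

    def test_interfacial_term_linear_in_gamma(self, ambient):
        R, n = 6.3, 10.0
        lo = ambient.with_delta(ambient.delta)
        hi = TheoryInputs(
            lo.temperature, lo.pressure, lo.rho, lo.kappa_T, lo.d_ww,
            2 * lo.gamma, lo.delta,
        )
        base = lo.Z * (mean_occupancy(R, lo) - n)
        assert mu_n_bubble(n, R, hi) - base == pytest.approx(
            2 * (mu_n_bubble(n, R, lo) - base), rel=1e-12
        )


class TestNStar:
    def test_closed_form_at_zero_Z_and_delta(self):
        """Closed form: n* = ⟨n⟩ − (4πρ/3)[3βγσ²/(2πρ²)]^{3/4}."""
        ti = TheoryInputs(pressure=0.0, gamma=66.3, delta=0.0)
        R = 6.3
        m = gaussian_model(R, ti)
        bg = ti.beta_gamma
        rb = (3.0 * bg * m.sigma2 / (2.0 * math.pi * ti.rho**2)) ** 0.25
        closed = m.mean - 4.0 * math.pi * ti.rho / 3.0 * rb**3
        assert n_star_numeric(R, ti) == pytest.approx(closed, abs=1e-10)
        assert n_star_series(R, ti) == pytest.approx(closed, abs=1e-12)

    def test_series_second_order_convergence(self, ambient):
        """Halving Z and δ shrinks the series error by at least 4x."""
        R = 6.3

        def err(pressure, delta):
            ti = TheoryInputs(
                ambient.temperature, pressure, ambient.rho, ambient.kappa_T,
                ambient.d_ww, ambient.gamma, delta,
            )
            return abs(n_star_series(R, ti) - n_star_numeric(R, ti))

        e_full = err(40.0, 0.8)
        e_half = err(20.0, 0.4)
        assert e_full > 0
        assert e_full / e_half >= 4.0

    def test_large_tension_small_cavity_gives_none(self):
        ti = TheoryInputs(gamma=500.0, delta=0.0)
        assert n_star_numeric(2.1, ti) is None

    def test_n_star_below_mean_whenever_it_exists(self, ambient):
        for R in (3.3, 4.3, 5.3, 6.3):
            ns = n_star_numeric(R, ambient)
            if ns is not None:
                assert ns < mean_occupancy(R, ambient)

    def test_series_monotone_decreasing_in_gamma(self, ambient):
        R = 6.3
        stars = []
        for g in (40.0, 55.0, 66.3, 80.0):
            ti = TheoryInputs(
                ambient.temperature, ambient.pressure, ambient.rho,
                ambient.kappa_T, ambient.d_ww, g, ambient.delta,
            )
            stars.append(n_star_series(R, ti))
        assert all(a > b for a, b in zip(stars, stars[1:]))


class TestAFT:
    def test_value_and_derivative_continuity_at_n_star(self, ambient):
        R = 6.3
        ns = n_star_numeric(R, ambient)
        assert ns is not None
        below = mu_n_aft(ns - 1e-9, R, ambient)
        above = mu_n_aft(ns + 1e-9, R, ambient)
        assert below == pytest.approx(above, abs=1e-6)
        eps_gap = float(mu_n_gaussian(ns, R, ambient)) - mu_n_bubble(ns, R, ambient, 0.0)
        assert mu_n_bubble(ns, R, ambient, eps_gap) == pytest.approx(
            float(mu_n_gaussian(ns, R, ambient)), abs=1e-12
        )
        # derivative continuity is the definition of n*
        assert removal_work_gaussian(ns, R, ambient) == pytest.approx(
            removal_work_bubble(ns, R, ambient), abs=1e-6
        )

    def test_gaussian_branch_above_n_star(self, ambient):
        R = 6.3
        ns = n_star_numeric(R, ambient)
        grid = np.linspace(ns + 0.5, mean_occupancy(R, ambient), 7)
        assert np.allclose(
            mu_n_aft(grid, R, ambient), mu_n_gaussian(grid, R, ambient), rtol=1e-12
        )

    def test_mu0_two_code_paths_agree(self, ambient):
        for R in (4.3, 5.3, 6.3):
            assert mu0_aft(R, ambient) == pytest.approx(
                float(mu_n_aft(0.0, R, ambient)), rel=1e-12
            )

    def test_pure_gaussian_when_no_bubble(self):
        ti = TheoryInputs(gamma=500.0, delta=0.0)
        R = 2.1
        assert mu0_aft(R, ti) == pytest.approx(mu0_igft(R, ti), rel=1e-12)
        n = np.arange(0, 4, dtype=float)
        assert np.allclose(mu_n_aft(n, R, ti), mu_n_gaussian(n, R, ti))

    def test_distribution_effectively_normalized(self, ambient):
        """n* sits ≳2σ below ⟨n⟩, so the Gaussian normalization carries over."""
        R = 6.3
        n = np.arange(0, 80, dtype=float)
        p = np.exp(-np.asarray(mu_n_aft(n, R, ambient)))
        assert p.sum() == pytest.approx(1.0, abs=0.05)

    def test_fat_tail_below_igft(self, ambient):
        # the bubble branch must lower the emptying cost for a large cavity
        assert mu0_aft(6.3, ambient) < mu0_igft(6.3, ambient)


class TestDeltaFit:
    radii = np.arange(2.5, 6.4, 0.4)

    def test_exact_recovery_at_zero_noise(self, ambient):
        truth = ambient.with_delta(0.5)
        data = [(R, mu0_aft(R, truth, series=True)) for R in self.radii]
        fitted, resid = fit_delta(data, ambient)
        assert fitted == pytest.approx(0.5, abs=1e-8)
        assert np.max(np.abs(resid)) < 1e-8

    def test_recovery_with_noise(self, ambient, rng):
        truth = ambient.with_delta(0.5)
        data = [
            (R, mu0_aft(R, truth, series=True) + rng.normal(0.0, 0.3), 0.3)
            for R in self.radii
        ]
        fitted, _ = fit_delta(data, ambient)
        assert fitted == pytest.approx(0.5, abs=0.15)

    def test_gaussian_regime_only_is_unidentifiable(self):
        ti = TheoryInputs(gamma=500.0)
        data = [(R, mu0_igft(R, ti)) for R in (2.0, 2.2, 2.4)]
        with pytest.raises(ValueError, match="flat objective"):
            fit_delta(data, ti)

    def test_too_few_points_rejected(self, ambient):
        with pytest.raises(ValueError):
            fit_delta([(3.0, 5.0), (4.0, 9.0)], ambient)


def test_surface_tension_temperature_correction():
    # 66.0 dyn/cm at 300 K shifts to ~66.3 dyn/cm at 25 °C
    assert corrected_surface_tension() == pytest.approx(66.3, abs=0.05)
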