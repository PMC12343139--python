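"""Closed forms for the normalized IFFL1 system against ODE oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cdrmotifs import (G_value, MotifSpec, SolverOptions,
                       boundary_integral_I, cdr_closed, dcdr_du_closed,
                       exp_integral, lemma_functions, sensitivity, simulate,
                       x_closed, y_closed)
from cdrmotifs.analytic_iffl1 import NormalizedIFFL1Input, phi


def _norm_spec(x0: float) -> MotifSpec:
    return MotifSpec("IFFL1", x0=x0, y0=1.0)


class TestXClosed:
    def test_endpoints(self):
        assert x_closed(0.0, 3.0, 0.5) == pytest.approx(0.5)
        assert x_closed(50.0, 3.0, 0.5) == pytest.approx(3.0)
        assert x_closed(2.0, 1.5, 1.5) == pytest.approx(1.5)

    def test_matches_simulation(self):
        traj = simulate(_norm_spec(0.7), 2.5, 6.0)
        closed = x_closed(traj.times, 2.5, 0.7)
        assert np.max(np.abs(closed - traj.x_values)) < 1e-9


class TestYClosed:
    def test_initial_and_stationary_values(self):
        assert y_closed(0.0, 2.0, 0.0) == 1.0
        for t in (0.5, 2.0, 7.0):
            assert y_closed(t, 1.3, 1.3) == 1.0

    @pytest.mark.parametrize("u,x0,t", [
        (2.0, 0.0, 1.5), (0.3, 1.2, 3.0), (10.0, 2.0, 0.7)])
    def test_matches_simulation(self, u, x0, t):
        traj = simulate(_norm_spec(x0), u, t,
                        SolverOptions(rtol=1e-10, atol=1e-13, n_points=3))
        assert y_closed(t, u, x0) == pytest.approx(
            float(traj.y_values[-1]), abs=1e-7)


class TestExpIntegral:
    def test_reference_value(self):
        # Ei(1) from the defining principal-value integral (independently
        # cross-checked by series expansion gamma + log|z| + sum z^n/(n n!))
        g = 0.5772156649015329
        series = g + sum(1.0 / (n * math.factorial(n)) for n in range(1, 30))
        assert exp_integral(1.0) == pytest.approx(series, abs=1e-12)

    def test_negative_axis_against_quadrature(self):
        # Ei(-x) = -E1(x) = -int_x^inf e^-w / w dw; tolerance set by the
        # quadrature oracle, not the implementation
        for x in (0.5, 1.0, 3.0):
            val, _ = quad(lambda w: math.exp(-w) / w, x, np.inf)
            assert exp_integral(-x) == pytest.approx(-val, rel=1e-8)

    def test_tail_and_singularity(self):
        # |Ei(-40)| < e^{-40}/40 (alternating asymptotic series bound)
        assert abs(exp_integral(-40.0)) < math.exp(-40.0) / 40.0
        assert exp_integral(-1e-8) < -17.0   # log divergence at 0^-
        with pytest.raises(ValueError):
            exp_integral(0.0)


class TestBoundaryIntegralI:
    @pytest.mark.parametrize("u,x0,T", [(2.0, 0.5, 3.0), (0.4, 1.5, 1.0)])
    def test_boundary_limits(self, u, x0, T):
        assert boundary_integral_I(T, T, u, x0) == pytest.approx(0.0,
                                                                 abs=1e-10)
        assert boundary_integral_I(1e-9, T, u, x0) == pytest.approx(
            T, abs=1e-6)

    def test_degenerate_case_u_equals_x0(self):
        assert boundary_integral_I(1.0, 3.0, 2.0, 2.0) == pytest.approx(2.0)

    def test_continuity_across_series_switchover(self):
        # the evaluation switches scheme when both Ei arguments are small;
        # values on either side of the switch must agree
        u, x0, T = 1.05, 1.0, 8.0   # kappa = 0.05 keeps arguments small
        s_vals = np.linspace(0.01, 7.99, 200)
        vals = [boundary_integral_I(s, T, u, x0) for s in s_vals]
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals, 2))) < 1e-3  # no jumps

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            boundary_integral_I(0.0, 1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            boundary_integral_I(1.5, 1.0, 2.0, 0.0)


class TestCdrClosed:
    def test_degenerate_case_is_exactly_T(self):
        assert cdr_closed(2.0, 2.0, 7.3) == 7.3

    def test_matches_augmented_state_simulation(self):
        traj = simulate(_norm_spec(0.0), 2.0, 1.5,
                        SolverOptions(rtol=1e-10, atol=1e-13))
        assert cdr_closed(2.0, 0.0, 1.5) == pytest.approx(traj.cdr,
                                                          rel=1e-9)

    def test_randomized_sweep_against_ode(self, rng):
        opts = SolverOptions(rtol=1e-10, atol=1e-13, n_points=3)
        for _ in range(25):
            u = float(10 ** rng.uniform(-2, np.log10(50)))
            x0 = float(rng.uniform(0.0, 10.0))
            T = float(rng.uniform(0.1, 20.0))
            sim = simulate(_norm_spec(x0), u, T, opts).cdr
            assert cdr_closed(u, x0, T) == pytest.approx(sim, rel=1e-7)

    def test_monotone_in_u(self):
        us = np.logspace(-1, 2, 25)
        vals = [cdr_closed(u, 1.7, 4.0) for u in us]
        assert np.all(np.diff(vals) > 0)

    def test_integration_by_parts_identity(self):
        """The Ei-boundary form (head integral + u ∫ e^{-us} I(s,T) ds)
        equals the simplified single-integral cDR expression."""
        for u, x0, T in [(2.0, 0.5, 3.0), (0.7, 2.0, 5.0), (5.0, 0.0, 1.5)]:
            kappa = u - x0
            head, _ = quad(
                lambda t: math.exp(kappa * (-math.expm1(-t)) - u * t),
                0.0, T, epsabs=1e-12, epsrel=1e-12)
            tail, _ = quad(
                lambda s: math.exp(-u * s) * boundary_integral_I(s, T, u, x0),
                1e-12, T, epsabs=1e-12, epsrel=1e-12, limit=200)
            assert head + u * tail == pytest.approx(cdr_closed(u, x0, T),
                                                    abs=1e-8)


class TestDcdrDuClosed:
    @pytest.mark.parametrize("u,x0,T", [
        (0.5, 0.0, 2.0), (2.0, 1.5, 4.0), (8.0, 3.0, 1.0), (1.0, 6.0, 10.0)])
    def test_non_negative_and_matches_finite_difference(self, u, x0, T):
        val = dcdr_du_closed(u, x0, T)
        assert val >= 0.0
        h = 1e-5 * u
        fd = (cdr_closed(u + h, x0, T) - cdr_closed(u - h, x0, T)) / (2 * h)
        assert val == pytest.approx(fd, abs=1e-5 * max(1.0, abs(val)))

    def test_equals_single_crossing_integrand_form(self):
        """d(cDR)/du = ∫ e^{-us} e^{κ(1-e^{-s})} f_κ(s) ds."""
        for u, x0, T in [(3.0, 1.0, 2.5), (1.2, 0.4, 6.0)]:
            kappa = u - x0
            val, _ = quad(
                lambda s: math.exp(-u * s)
                * math.exp(kappa * (-math.expm1(-s)))
                * lemma_functions(s, kappa, T)[1],
                0.0, T, epsabs=1e-12, epsrel=1e-12, limit=200)
            assert dcdr_du_closed(u, x0, T) == pytest.approx(val, abs=1e-8)

    def test_infinite_horizon_limit_matches_G_derivative_integrand(self):
        """At x0 = 0 and T → ∞ the derivative approaches the positive
        integral ∫ e^{-us}(s/(1-e^{-s}) - e^{u(1-e^{-s})}(s/(1-e^{-s})-1))ds."""
        u = 1.5

        def integrand(s):
            r = s / (-math.expm1(-s)) if s else 1.0
            return math.exp(-u * s) * (
                r - math.exp(u * (-math.expm1(-s))) * (r - 1.0))

        limit_val, _ = quad(integrand, 0.0, np.inf, epsabs=1e-12,
                            epsrel=1e-12, limit=200)
        assert dcdr_du_closed(u, 0.0, 40.0) == pytest.approx(limit_val,
                                                             abs=1e-6)
        assert limit_val > 0


class TestLemmaFunctions:
    def test_rho_vanishes_at_boundaries(self):
        for T in (1.0, 5.0):
            assert lemma_functions(0.0, 2.0, T)[0] == 0.0
            assert lemma_functions(T, 2.0, T)[0] == pytest.approx(0.0)

    def test_f_kappa_boundary_values(self):
        for kappa, T in [(0.5, 2.0), (4.0, 6.0)]:
            _, f0, _ = lemma_functions(1e-10, kappa, T)
            assert f0 == pytest.approx(1.0 - math.exp(-T), abs=1e-6)
            _, fT, _ = lemma_functions(T, kappa, T)
            assert fT == pytest.approx(0.0, abs=1e-12)

    def test_phi_limit_and_derivative_bounds(self):
        assert phi(0.0) == 1.0
        assert phi(1e-12) == pytest.approx(1.0)
        z = np.linspace(1e-6, 20.0, 2000)
        vals = np.array([phi(v) for v in z])
        dphi = np.gradient(vals, z)
        assert dphi.max() < 1e-6          # phi' <= 0
        assert dphi.min() > -1.0 - 1e-6   # phi' >= -1

    @pytest.mark.parametrize("kappa,T", [(0.5, 3.0), (2.0, 8.0),
                                         (10.0, 2.0), (25.0, 15.0)])
    def test_single_sign_change(self, kappa, T):
        s = np.linspace(1e-9, T, 4000)
        f = np.array([lemma_functions(v, kappa, T)[1] for v in s])
        signs = np.sign(f[np.abs(f) > 1e-13])
        changes = np.count_nonzero(np.diff(signs))
        assert changes <= 1


class TestGValue:
    @pytest.mark.parametrize("u", [0.5, 1.0, 2.0, 10.0])
    def test_series_and_integral_agree(self, u):
        assert G_value(u, "series") == pytest.approx(
            G_value(u, "integral"), abs=1e-8)

    def test_increasing(self):
        us = np.logspace(-1, 1.5, 20)
        vals = [G_value(u) for u in us]
        assert np.all(np.diff(vals) > 0)

    def test_derivative_positive_and_matches_sensitivity_integral(self):
        u, h = 2.0, 1e-6
        dG = (G_value(u + h) - G_value(u - h)) / (2 * h)
        assert dG > 0
        # dG/du is the infinite-horizon cDR sensitivity at x0 = 0
        assert dG == pytest.approx(dcdr_du_closed(u, 0.0, 40.0), abs=1e-6)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            G_value(-1.0)
        with pytest.raises(ValueError):
            G_value(1.0, method="magic")


class TestNormalizedInput:
    def test_kappa_definition_and_validation(self):
        inp = NormalizedIFFL1Input(u=3.0, x0=1.2, T=2.0)
        assert inp.kappa == pytest.approx(1.8)
        with pytest.raises(ValueError):
            NormalizedIFFL1Input(u=-1.0, x0=0.0, T=1.0)


class TestSensitivityConsistency:
    def test_closed_form_derivative_matches_variational_ode(self):
        """dcdr_du_closed equals the forward-sensitivity cDR derivative."""
        u, x0, T = 2.0, 0.6, 3.0
        sens = sensitivity(_norm_spec(x0), u, T,
                           SolverOptions(rtol=1e-10, atol=1e-13))
        assert dcdr_du_closed(u, x0, T) == pytest.approx(sens.dcdr_du,
                                                         abs=1e-7)
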