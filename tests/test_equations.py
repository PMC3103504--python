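"""Right-hand-side functions: limiting cases, monotonicity, consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from granulosim import (DetailedParams, MinimalParams,
                        detailed_drives, detailed_rhs, hill_activation,
                        minimal_drive, minimal_rhs)

nonneg = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestMinimalDrive:
    def test_zero_inputs_zero_drive(self):
        p = MinimalParams(eta1=1.0, eta2=1.0, c=0.0)
        assert minimal_drive(0.0, p) == 0.0

    def test_linear_combination(self, fig1_params):
        # A=4 with eta1=eta2=1, c=3
        assert minimal_drive(4.0, fig1_params) == pytest.approx(7.0)

    def test_zero_coefficients(self):
        p = MinimalParams(eta1=0.0, eta2=0.0, c=5.0)
        for A in (0.0, 1.0, 100.0):
            assert minimal_drive(A, p) == 0.0

    def test_negative_antigen_rejected(self, fig1_params):
        with pytest.raises(ValueError):
            minimal_drive(-1.0, fig1_params)


class TestHillActivation:
    def test_no_drive_no_activation(self):
        for x in (0.0, 0.5, 10.0):
            assert hill_activation(x, 0.0, 1.0) == 0.0

    def test_no_seed_no_autocatalysis(self):
        for f in (0.0, 3.0, 100.0):
            assert hill_activation(0.0, f, 1.0) == 0.0

    def test_saturating_plateau_equals_drive(self):
        assert hill_activation(1e8, 3.0, 1.0) == pytest.approx(3.0, rel=1e-10)

    def test_zero_theta_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(1.0, 1.0, 0.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x1=nonneg, x2=nonneg, f=nonneg,
           theta=st.floats(min_value=0.05, max_value=10.0))
    def test_nondecreasing_in_x_and_linear_in_f(self, x1, x2, f, theta):
        lo, hi = sorted((x1, x2))
        assert hill_activation(lo, f, theta) <= hill_activation(hi, f, theta) + 1e-12
        assert hill_activation(x1, 2.0 * f, theta) == pytest.approx(
            2.0 * hill_activation(x1, f, theta), abs=1e-12)


class TestMinimalRhs:
    def test_basal_steady_state(self):
        # with f_T = 0 the rate vanishes exactly at T = beta/eps
        p = MinimalParams(beta_T=0.02, eps_T=1.0, eta1=0.0, eta2=0.0, c=0.0)
        assert minimal_rhs(p.beta_T / p.eps_T, 0.0, p) == pytest.approx(0.0, abs=1e-15)

    def test_pure_influx_at_zero(self, fig1_params):
        assert minimal_rhs(0.0, 5.0, fig1_params) == fig1_params.beta_T

    def test_sign_changes_across_the_three_roots(self, fig1_params):
        """Inside the bistable range the rate changes sign at each root of
        the steady-state cubic (checked against a brentq root oracle)."""
        p = fig1_params  # f_T = 3 at A=0 lies in the bistable range
        g = lambda T: minimal_rhs(T, 0.0, p)
        grid = np.linspace(0.0, 5.0, 2001)
        vals = np.array([g(T) for T in grid])
        roots = [brentq(g, grid[i], grid[i + 1])
                 for i in range(len(grid) - 1) if vals[i] * vals[i + 1] < 0]
        assert len(roots) == 3
        low, mid, high = roots
        assert g(0.5 * (low + mid)) < 0 < g(0.5 * (mid + high))
        assert g(high + 1.0) < 0


class TestDetailedDrives:
    def test_all_zero_state_zero_drives(self, base_detailed):
        d = detailed_drives(np.zeros(6), 0.0, base_detailed)
        assert (d.f_T, d.f_R, d.f_M) == (0.0, 0.0, 0.0)

    def test_doubling_tregs_strictly_decreases_teff_drive(self, base_detailed):
        y = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
        y2 = y.copy()
        y2[1] *= 2.0
        assert (detailed_drives(y2, 1.0, base_detailed).f_T
                < detailed_drives(y, 1.0, base_detailed).f_T)

    def test_drive_linear_without_treg_inhibition(self, base_detailed):
        p = base_detailed.with_(k_1d=0.0)
        y1 = np.array([1.0, 2.0, 1.0, 0.3, 0.4, 0.0])
        y2 = np.array([1.0, 2.0, 2.0, 0.6, 0.8, 0.0])  # doubled A*M, delta, gamma
        f1 = detailed_drives(y1, 1.0, p).f_T
        f2 = detailed_drives(y2, 2.0, p).f_T  # A doubled too: A*M quadruples
        expected = (p.k_1a * 4.0 + p.k_1b * 0.6 + p.k_1c * 0.8)
        assert f2 == pytest.approx(expected)
        assert f1 == pytest.approx(p.k_1a * 1.0 + p.k_1b * 0.3 + p.k_1c * 0.4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(y=st.lists(st.floats(min_value=0.0, max_value=20.0), min_size=6, max_size=6),
           A=st.floats(min_value=0.0, max_value=100.0))
    def test_drives_nonnegative_and_monotone(self, y, A):
        p = DetailedParams()
        d = detailed_drives(y, A, p)
        assert d.f_T >= 0 and d.f_R >= 0 and d.f_M >= 0
        # f_T nondecreasing in antigen, IL-2 and IFN-gamma
        y_up = list(y)
        y_up[3] += 1.0
        y_up[4] += 1.0
        assert detailed_drives(y_up, A + 1.0, p).f_T >= d.f_T
        # f_R nondecreasing in IL-2, nonincreasing in TNF-alpha
        y_a = list(y)
        y_a[5] += 1.0
        assert detailed_drives(y_a, A, p).f_R <= d.f_R


class TestDetailedRhs:
    def test_all_zero_state_gives_basal_influx(self, base_detailed):
        dy = detailed_rhs(np.zeros(6), 0.0, (0.0, 0.0, 0.0), base_detailed)
        p = base_detailed
        expected = [p.beta_T, p.beta_R, p.beta_M,
                    p.beta_delta, p.beta_gamma, p.beta_alpha]
        assert dy == pytest.approx(expected)

    def test_il2_basal_root_matches_initial_condition(self, base_detailed):
        """With T = 0 the IL-2 equation reduces to beta - eps*delta, whose
        root beta/eps = 0.001 is exactly the published initial condition."""
        p = base_detailed
        y = np.zeros(6)
        y[3] = p.beta_delta / p.eps_delta
        dy = detailed_rhs(y, 0.0, (0.0, 0.0, 0.0), p)
        assert dy[3] == pytest.approx(0.0, abs=1e-15)
        assert p.beta_delta / p.eps_delta == pytest.approx(0.001)

    def test_cytokine_quasi_steady_state_closed_form(self, base_detailed):
        """With cell densities frozen, each cytokine relaxes to
        (beta + production)/(eps + inhibitor), matching the closed form."""
        p = base_detailed
        T, M = 4.0, 7.0
        I = (2.0, 5.0, 0.0)

        def rhs(t, y):
            full = np.array([T, 0.0, M, y[0], y[1], y[2]])
            return detailed_rhs(full, 0.0, I, p)[3:]

        sol = solve_ivp(rhs, (0, 20), [0.001, 0.001, 0.001],
                        rtol=1e-10, atol=1e-12)
        got = sol.y[:, -1]
        expected = [
            (p.beta_delta + p.k_3 * T) / (p.eps_delta + I[0]),
            (p.beta_gamma + p.k_4a * T + p.k_4b * M) / (p.eps_gamma + I[1]),
            (p.beta_alpha + p.k_5a * T + p.k_5b * M) / (p.eps_alpha + I[2]),
        ]
        assert got == pytest.approx(expected, rel=1e-8)

    def test_reduces_to_minimal_form_with_frozen_environment(self, base_detailed):
        """Freezing R, M, delta, gamma, alpha reduces dT/dt to the minimal
        structure: basal influx - clearance + Hill(drive)."""
        p = base_detailed
        y = np.array([0.7, 1.3, 2.0, 0.4, 0.6, 0.9])
        dy = detailed_rhs(y, 2.0, (0.0, 0.0, 0.0), p)
        d = detailed_drives(y, 2.0, p)
        manual = (p.beta_T - (p.eps_T + p.k_1e * y[5]) * y[0]
                  + hill_activation(y[0], d.f_T, p.theta_T))
        assert dy[0] == pytest.approx(manual, rel=1e-12)
        # and the Hill term itself is the minimal-model form
        mp = MinimalParams(theta_T=p.theta_T, beta_T=p.beta_T, eps_T=p.eps_T,
                           eta1=0.0, eta2=1.0, c=d.f_T)
        assert (minimal_rhs(y[0], 0.0, mp)
                == pytest.approx(dy[0] + p.k_1e * y[5] * y[0], rel=1e-12))

    def test_negative_inhibitor_rejected(self, base_detailed):
        with pytest.raises(ValueError):
            detailed_rhs(np.zeros(6), 0.0, (-1.0, 0.0, 0.0), base_detailed)
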