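"""Flux expressions, right-hand sides and their analytic Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcellca as t
from tcellca._jacobian import sympy_jacobian
from tcellca.parameters import PARAM_ORDER


@pytest.fixture(scope="module")
def params():
    return t.Parameters(V_PLC=0.1, delta=2.0)


def random_open_states(rng, n, params):
    c = rng.uniform(0.0, 1.0, n)
    c_e = rng.uniform(1.0, 1000.0, n)
    h = rng.uniform(0.0, 1.0, n)
    p = rng.uniform(0.0, 2.0, n)
    s = rng.uniform(0.0, params.V_SOCE, n)
    return np.stack([c, c_e, h, p, s], axis=1)


class TestStoreOperatedInflux:
    def test_midpoint_is_half_maximal(self, params):
        assert t.j_soce(params.K_e, params) == pytest.approx(
            params.V_SOCE / 2, abs=1e-12)

    def test_empty_store_saturates(self, params):
        assert abs(t.j_soce(0.0, params) - params.V_SOCE) < 1e-6

    def test_scalar_value_above_midpoint(self):
        # independent evaluation: V/(1+e^{s1*(850-800)}) with V=3, s1=0.2
        p = t.Parameters(V_PLC=0.1, delta=2.0, V_SOCE=3.0, s1=0.2, K_e=800.0)
        assert t.j_soce(850.0, p) == pytest.approx(3.0 / (1.0 + np.exp(10.0)),
                                                   rel=1e-12)

    def test_monotone_decreasing_on_grid(self, params):
        ce = np.linspace(0.0, 2000.0, 1000)
        vals = t.j_soce(ce, params)
        # non-increasing everywhere (the sigmoid underflows to exactly
        # V_SOCE / 0 far from the midpoint in floating point), strictly
        # decreasing where it is representable
        assert np.all(np.diff(vals) <= 0)
        mid = (ce > 700) & (ce < 900)
        assert np.all(np.diff(vals[mid]) < 0)
        assert np.all(vals >= 0) and np.all(vals <= params.V_SOCE)
        assert t.j_soce(params.K_e, params) == params.V_SOCE / 2

    def test_rejects_bad_input(self, params):
        with pytest.raises(ValueError):
            t.j_soce(np.nan, params)
        with pytest.raises(ValueError):
            t.j_soce(-1.0, params)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ce=st.floats(0.0, 5000.0))
    def test_bounded_for_any_store_load(self, ce):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        v = float(t.j_soce(ce, p))
        assert 0.0 <= v <= p.V_SOCE


class TestIP3Degradation:
    def test_zero_at_zero_calcium(self, params):
        assert t.j_deg(0.0, 5.0, params) == 0.0

    def test_half_saturation(self, params):
        assert t.j_deg(params.K_deg, 1.0, params) == pytest.approx(
            params.V_deg / 2, rel=1e-12)

    def test_saturates_at_high_calcium(self, params):
        assert t.j_deg(1e6, 1.0, params) == pytest.approx(params.V_deg,
                                                          rel=1e-6)

    def test_linear_in_ip3(self, params):
        assert t.j_deg(0.3, 2.0, params) == pytest.approx(
            2.0 * t.j_deg(0.3, 1.0, params), rel=1e-12)

    def test_rejects_negative_input(self, params):
        with pytest.raises(ValueError):
            t.j_deg(-0.1, 1.0, params)
        with pytest.raises(ValueError):
            t.j_deg(0.1, -1.0, params)


class TestFluxBreakdown:
    def test_probability_and_timescale_bounds(self, params, rng=None):
        rng = np.random.default_rng(7)
        states = random_open_states(rng, 10_000, params)
        P0, h_inf, tau_h = t.ip3r_gating(states[:, 0], states[:, 3],
                                         states[:, 2], params)
        assert np.all((P0 >= 0) & (P0 <= 1))
        assert np.all((h_inf >= 0) & (h_inf <= 1))
        assert np.all(tau_h > 0)

    def test_unidirectional_fluxes_nonnegative(self, params):
        rng = np.random.default_rng(8)
        states = random_open_states(rng, 1000, params)
        assert np.all(t.j_pm(states[:, 0], params) >= 0)
        assert np.all(t.j_soce(states[:, 1], params) >= 0)
        assert np.all(t.j_deg(states[:, 0], states[:, 3], params) >= 0)

    def test_serca_reverses_only_at_depleted_cytosol(self, params):
        # the bidirectional pump runs backwards iff c^2 < K_bar * c_e^2
        rng = np.random.default_rng(9)
        states = random_open_states(rng, 1000, params)
        c, ce = states[:, 0], states[:, 1]
        vals = t.j_serca(c, ce, params)
        assert np.all((vals < 0) == (c**2 < params.K_bar * ce**2))

    def test_unstimulated_high_load_state_has_no_influx(self, params):
        # with the store loaded to 850 µM the CRAC influx is fully off
        fb = t.er_fluxes(t.OpenState(c=0.0850, c_e=850.0, h=0.95, p=0.0,
                                     s=0.0), params)
        assert fb.J_SOCE < 1e-3
        assert fb.P0 == 0.0

    def test_open_closed_agreement_under_substitution(self):
        # closed-cell flux forms with c_e eliminated must equal the
        # open-cell forms evaluated at c_e = gamma (C_t - c)
        rng = np.random.default_rng(10)
        p = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
        for _ in range(100):
            c = rng.uniform(0.0, 1.0)
            h = rng.uniform(0.0, 1.0)
            pp = rng.uniform(0.0, 2.0)
            c_e = p.gamma * (p.C_t - c)
            fb_open = t.er_fluxes(t.OpenState(c, c_e, h, pp, 0.0), p)
            fb_closed = t.er_fluxes(t.ClosedState(c, h, pp), p)
            for name in ("J_IP3R", "J_SERCA", "P0", "h_inf", "tau_h"):
                assert abs(getattr(fb_open, name) -
                           getattr(fb_closed, name)) < 1e-12


class TestRightHandSides:
    def test_closed_cell_conservation_identity(self):
        # delta = 0 implies d/dt (c + c_e/gamma) = 0 identically
        rng = np.random.default_rng(11)
        p = t.Parameters(V_PLC=0.1, delta=0.0)
        states = random_open_states(rng, 200, p)
        for y in states:
            dy = t.rhs_open(0.0, y, p)
            assert abs(dy[0] + dy[1] / p.gamma) < 1e-13

    def test_closed_rhs_equals_open_rhs_under_substitution(self):
        rng = np.random.default_rng(12)
        p = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
        for _ in range(100):
            c = rng.uniform(0.0, 1.0)
            h = rng.uniform(0.0, 1.0)
            pp = rng.uniform(0.0, 2.0)
            y_closed = np.array([c, h, pp])
            y_open = np.array([c, p.gamma * (p.C_t - c), h, pp, 0.5])
            d_closed = t.rhs_closed(0.0, y_closed, p)
            d_open = t.rhs_open(0.0, y_open, p)
            assert np.max(np.abs(d_closed - d_open[[0, 2, 3]])) < 1e-12

    def test_unstimulated_high_load_crac_formation_rate(self):
        # ds/dt = (J_SOCE - s)/tau_s at the fully loaded resting state
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        dy = t.rhs_open(0.0, np.array([0.0850, 850.0, 0.95, 0.0, 0.0]), p)
        assert dy[4] == pytest.approx(t.j_soce(850.0, p) / p.tau_s, rel=1e-9)
        assert dy[4] == pytest.approx(9.1e-6, rel=0.01)

    def test_rejects_invalid_states(self):
        p = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
        with pytest.raises(ValueError):
            t.rhs_open(0.0, np.array([np.nan, 800, 0.5, 0.1, 1.0]), p)
        with pytest.raises(ValueError):
            t.rhs_closed(0.0, np.array([150.0, 0.5, 0.1]), p)

    def test_state_validation(self):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        with pytest.raises(ValueError):
            t.OpenState(0.1, 800.0, 1.5, 0.1, 1.0).validate()
        with pytest.raises(ValueError):
            t.OpenState(0.1, 800.0, 0.5, 0.1, 5.0).validate(p)
        with pytest.raises(ValueError):
            t.ClosedState(150.0, 0.5, 0.1).validate(p)


class TestJacobians:
    @pytest.mark.parametrize("model", ["open", "closed"])
    def test_kernel_jacobian_matches_finite_differences(self, model):
        rng = np.random.default_rng(13)
        p = t.Parameters(V_PLC=0.1, delta=2.0, C_t=140.0)
        jac = t.jac_open if model == "open" else t.jac_closed
        rhs = t.rhs_open if model == "open" else t.rhs_closed
        n = 5 if model == "open" else 3
        for _ in range(20):
            y = (random_open_states(rng, 1, p)[0] if model == "open"
                 else np.array([rng.uniform(0, 1), rng.uniform(0, 1),
                                rng.uniform(0, 2)]))
            J = jac(0.0, y, p)
            J_fd = np.empty((n, n))
            for j in range(n):
                h = 1e-6 * (1.0 + abs(y[j]))
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                J_fd[:, j] = (rhs(0.0, yp, p) - rhs(0.0, ym, p)) / (2 * h)
            assert np.max(np.abs(J - J_fd)) < 1e-4 * (1 + np.max(np.abs(J)))

    @pytest.mark.parametrize("model", ["open", "closed"])
    def test_kernel_jacobian_matches_symbolic(self, model):
        rng = np.random.default_rng(14)
        p = t.Parameters(V_PLC=0.1, delta=2.0, C_t=140.0)
        jac = t.jac_open if model == "open" else t.jac_closed
        for _ in range(5):
            y = (random_open_states(rng, 1, p)[0] if model == "open"
                 else np.array([rng.uniform(0, 1), rng.uniform(0, 1),
                                rng.uniform(0, 2)]))
            assert np.max(np.abs(jac(0.0, y, p) -
                                 sympy_jacobian(model, y, p))) < 1e-10

    def test_parameter_vector_ordering_is_consistent(self):
        from tcellca import _kernels
        assert _kernels.PARAM_ORDER == PARAM_ORDER
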