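"""Equilibrium continuation, Hopf localization and codim-2 curves."""

import numpy as np
import pytest
from scipy.optimize import brentq

import tcellca as t
from tcellca.continuation import continue_equilibria
from tcellca.systems import CustomSystem


MU_STAR = 0.123
OMEGA = 2.0


@pytest.fixture(scope="module")
def normal_form_branch():
    """A decoupled linear system with an analytically placed crossing."""

    def rhs(y, params):
        a = params.V_PLC - MU_STAR
        return np.array([a * y[0] - OMEGA * y[1],
                         OMEGA * y[0] + a * y[1],
                         -y[2]])

    sys = CustomSystem(n_vars=3, rhs=rhs, name="hopf-normal-form")
    return continue_equilibria(sys, t.Parameters(V_PLC=0.0, delta=0.0),
                               "V_PLC", (0.0, 0.3), np.zeros(3),
                               loc_tol=1e-8)


class TestHopfNormalFormOracle:
    MU_STAR = MU_STAR
    OMEGA = OMEGA

    def test_hopf_located_at_exact_crossing(self, normal_form_branch):
        hbs = normal_form_branch.hopf_points()
        assert len(hbs) == 1
        assert abs(hbs[0].par_value - self.MU_STAR) < 1e-6
        assert abs(abs(hbs[0].omega) - self.OMEGA) < 1e-6

    def test_stability_flags_flip_at_the_crossing(self, normal_form_branch):
        below = normal_form_branch.par_values < self.MU_STAR
        assert np.all(normal_form_branch.stable[below])
        assert not np.any(normal_form_branch.stable[~below])


class TestOpenCellDiagram:
    def test_two_hopf_points_with_stability_outside(self, open_eq_branch):
        hbs = open_eq_branch.hopf_points()
        assert len(hbs) == 2
        assert np.max(np.abs(
            [np.max(np.abs(t.rhs_open(0.0, y, open_eq_branch.params.replace(
                V_PLC=float(pv))))) for pv, y in
             zip(open_eq_branch.par_values, open_eq_branch.states)])) < 1e-8
        p1, p2 = sorted(h.par_value for h in hbs)
        inside = (open_eq_branch.par_values > p1 + 1e-3) & \
                 (open_eq_branch.par_values < p2 - 1e-3)
        outside = (open_eq_branch.par_values < p1 - 1e-3) | \
                  (open_eq_branch.par_values > p2 + 1e-3)
        assert not np.any(open_eq_branch.stable[inside])
        assert np.all(open_eq_branch.stable[outside])

    def test_hopf_point_carries_pure_imaginary_pair(self, open_eq_branch):
        for hb in open_eq_branch.hopf_points():
            cplx = hb.eigenvalues[np.abs(hb.eigenvalues.imag) > 1e-9]
            assert np.min(np.abs(cplx.real)) < 1e-6
            assert abs(hb.omega) > 0

    def test_detected_points_invariant_to_step_halving(self, s1_eq_branch):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        start = t.stimulated_equilibrium("open", p).state
        fine = continue_equilibria("open", p, "s1", (0.3, 0.1), start,
                                   ds0=5e-4, ds_max=1e-2)
        hb_a = s1_eq_branch.hopf_points()[0].par_value
        hb_b = fine.hopf_points()[0].par_value
        assert abs(hb_a - hb_b) < 1e-4


class TestTwoParameterHopfCurves:
    def test_curve_points_satisfy_one_parameter_test(self, s1_vplc_curve):
        """Every 10th curve point re-localized at frozen V_PLC."""
        curve = s1_vplc_curve
        p0 = curve.params

        def re_localize(s1_guess, v_plc, state):
            def g(s1v):
                p = p0.replace(s1=float(s1v), V_PLC=float(v_plc))
                eq = t.find_equilibrium("open", p, state)
                cplx = eq.eigenvalues[np.abs(eq.eigenvalues.imag) > 1e-9]
                return float(np.max(cplx.real))
            lo, hi = s1_guess - 5e-3, s1_guess + 5e-3
            return brentq(g, lo, hi, xtol=1e-8)

        checked = 0
        for i in range(0, curve.p1_values.size, 10):
            s1v, vv = curve.p1_values[i], curve.p2_values[i]
            if not (0.08 <= s1v <= 0.5):
                continue
            try:
                s1_ref = re_localize(s1v, vv, curve.states[i])
            except ValueError:
                continue   # test function does not bracket at frozen V_PLC
            assert abs(s1_ref - s1v) < 1e-4
            checked += 1
        assert checked >= 5

    def test_hopf_curve_passes_through_one_parameter_point(
            self, s1_eq_branch, s1_vplc_curve):
        hb = s1_eq_branch.hopf_points()[0]
        d = np.hypot(s1_vplc_curve.p1_values - hb.par_value,
                     s1_vplc_curve.p2_values - 0.1)
        assert d.min() < 5e-3

    def test_delay_region_is_bounded(self, taus_vplc_curve):
        assert taus_vplc_curve.closed
        assert not taus_vplc_curve.truncated
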