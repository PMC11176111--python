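"""Integration, equilibria and the stimulation scenario."""

import numpy as np
import pytest

import tcellca as t


class TestIntegrate:
    def test_closed_cell_conserves_total_calcium(self):
        p = t.Parameters(V_PLC=0.1, delta=0.0)
        init = np.array([0.08, 770.0, 0.9, 0.0, 0.4])
        traj = t.integrate("open", p, init, 1000.0, dt_out=0.5)
        ct = traj.total_calcium()
        assert np.max(np.abs(ct - ct[0])) < 1e-6

    def test_unstimulated_equilibrium_is_a_fixed_point(self):
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        eq = t.unstimulated_equilibrium("open", p)
        assert eq.stable
        traj = t.integrate("open", p, eq.state, 200.0, dt_out=1.0)
        assert np.max(np.abs(traj.states - eq.state[:, None])) < 1e-6

    def test_closed_matches_open_at_delta_zero(self):
        p = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
        eq = t.unstimulated_equilibrium("closed", p)
        c0, h0, p0 = eq.state
        y_open = np.array([c0, p.gamma * (p.C_t - c0), h0, p0, 0.0])
        tr_c = t.integrate("closed", p, eq.state, 60.0, dt_out=0.01)
        tr_o = t.integrate("open", p, y_open, 60.0, dt_out=0.01)
        assert np.max(np.abs(tr_c.c - tr_o.c)) < 1e-5

    def test_deterministic_repeatability(self):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        init = t.unstimulated_equilibrium("open", p).state
        a = t.integrate("open", p, init, 50.0, dt_out=0.05)
        b = t.integrate("open", p, init, 50.0, dt_out=0.05)
        assert np.array_equal(a.states, b.states)

    def test_invalid_inputs(self):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        with pytest.raises(ValueError):
            t.integrate("open", p, np.zeros(5), 0.0)
        with pytest.raises(ValueError):
            t.integrate("open", p, np.full(5, np.nan), 10.0)
        with pytest.raises(ValueError):
            t.integrate("open", p, np.zeros(3), 10.0)


class TestEquilibria:
    def test_newton_residual_and_return_after_perturbation(self):
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        eq = t.unstimulated_equilibrium("open", p)
        assert np.max(np.abs(t.rhs_open(0.0, eq.state, p))) < 1e-9
        assert eq.residual < 1e-10
        perturbed = eq.state + 1e-3
        traj = t.integrate("open", p, perturbed, 300.0, dt_out=1.0)
        assert np.max(np.abs(traj.states[:, -1] - eq.state)) < 1e-4

    def test_homotopy_reaches_unstable_stimulated_equilibrium(self):
        # at V_PLC = 0.1 (inside the oscillatory window) the equilibrium
        # exists but is unstable; direct Newton from rest does not reach it
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        eq = t.stimulated_equilibrium("open", p)
        assert not eq.stable
        assert np.max(np.abs(t.rhs_open(0.0, eq.state, p))) < 1e-9

    def test_nonconvergence_raises(self):
        p = t.Parameters(V_PLC=0.1, delta=2.0)
        with pytest.raises((RuntimeError, ValueError)):
            t.find_equilibrium("open", p, np.array([50.0, 1e5, 0.5, 30.0,
                                                    2.0]), max_iter=3)


class TestUnstimulatedBalance:
    def test_resting_state_scales_with_store_load(self):
        # at rest (p = 0, IP3R shut) the SERCA balance fixes
        # c = sqrt(K_bar) * c_e and the CRAC balance fixes s = J_SOCE(c_e)
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        c, s = t.unstimulated_partial_equilibrium(850.0, p)
        assert c == pytest.approx(np.sqrt(p.K_bar) * 850.0, rel=1e-9)
        assert s < 1e-3
        c, s = t.unstimulated_partial_equilibrium(809.0, p)
        assert c == pytest.approx(0.0809, rel=1e-6)
        assert s == pytest.approx(float(t.j_soce(809.0, p)), abs=1e-12)

    def test_rejects_bad_store_load(self):
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        with pytest.raises(ValueError):
            t.unstimulated_partial_equilibrium(-5.0, p)


class TestFeatureRobustness:
    def test_period_invariant_to_output_sampling(self):
        p = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
        init = t.unstimulated_equilibrium("closed", p).state
        periods = []
        for dt in (0.01, 0.05):
            traj = t.integrate("closed", p, init, 150.0, dt_out=dt)
            periods.append(t.extract_features(traj, p).period)
        assert abs(periods[0] - periods[1]) / periods[0] < 0.005

    def test_steady_trajectory_classified_steady(self):
        p = t.Parameters(V_PLC=0.0, delta=2.0)
        eq = t.unstimulated_equilibrium("open", p)
        traj = t.integrate("open", p, eq.state, 100.0, dt_out=0.05)
        f = t.extract_features(traj, p)
        assert not f.oscillating
        assert f.regime == "steady"
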