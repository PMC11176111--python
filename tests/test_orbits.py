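"""Periodic-orbit solving, Floquet stability and branch bifurcations."""

import numpy as np
import pytest

import tcellca as t
from tcellca.orbits import orbit_from_hopf


class TestOrbitQuality:
    def test_residual_below_bvp_tolerance(self, open_po_branch):
        assert all(o.residual < 1e-8 for o in open_po_branch.orbits)

    def test_trivial_multiplier_on_every_orbit(self, open_po_branch,
                                               closed_branches):
        # the autonomous system always carries one Floquet multiplier at 1
        for o in open_po_branch.orbits:
            assert abs(o.trivial_multiplier - 1.0) < 1e-3
        _, po140 = closed_branches[140.0]
        for o in po140.orbits:
            assert abs(o.trivial_multiplier - 1.0) < 1e-3

    def test_continued_period_matches_simulation(self, closed_branches):
        # pick a stable mid-branch orbit and compare with a long simulation
        _, po = closed_branches[140.0]
        i = int(np.argmin(np.abs(po.par_values - 0.1)))
        orbit = po.orbits[i]
        p = orbit.params
        init = t.unstimulated_equilibrium("closed", p).state
        traj = t.integrate("closed", p, init, 200.0, dt_out=0.005)
        feats = t.extract_features(traj, p)
        assert abs(feats.period - orbit.period) / orbit.period < 0.01


class TestHopfConsistency:
    def test_emergent_period_tends_to_linearized_period(self, open_eq_branch):
        # an orbit pinned at amplitude 1e-3 must have period within 2% of
        # 2*pi/omega at its Hopf point
        for hb in open_eq_branch.hopf_points():
            orb = orbit_from_hopf("open", open_eq_branch.params, hb,
                                  amplitude=1e-3, n_nodes=20)
            T_lin = 2.0 * np.pi / abs(hb.omega)
            assert abs(orb.period - T_lin) / T_lin < 0.02
            assert abs(float(getattr(orb.params, "V_PLC")) -
                       hb.par_value) < 1e-3


class TestClosedCellBifurcations:
    def test_supercritical_window_is_fully_stable(self, closed_branches):
        eq, po = closed_branches[140.0]
        assert len(eq.hopf_points()) == 2
        assert not po.detected("PD")
        assert all(po.stable)
        # the orbit branch spans the window between the two Hopf points
        h1, h2 = sorted(h.par_value for h in eq.hopf_points())
        assert po.par_values.min() < h1 + 0.005
        assert po.par_values.max() > h2 - 0.005

    def test_subcritical_window_has_folds_and_doublings(self, closed_branches):
        eq, po = closed_branches[95.0]
        snpo = sorted(q.par_value for q in po.detected("SNPO"))
        pd = sorted(q.par_value for q in po.detected("PD"))
        assert len(snpo) == 2
        assert len(pd) >= 2
        # stability holds exactly between the left fold and the first
        # period doubling
        stable_pars = po.par_values[po.stable]
        seg = stable_pars[(stable_pars > snpo[0] - 1e-3) &
                          (stable_pars < pd[0] + 1e-3)]
        assert seg.size > 0
        inner = (po.par_values > snpo[0] + 2e-3) & \
                (po.par_values < pd[0] - 2e-3) & \
                (np.array([np.ptp(o.nodes[:, 0]) for o in po.orbits]) > 0.05)
        assert np.all(po.stable[inner])
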