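"""Shared fixtures: the expensive simulations, branches and curves are
computed once per session and reused across the unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import tcellca as t
from tcellca.continuation import continue_equilibria, continue_hopf_2par
from tcellca.orbits import continue_periodic_orbits, orbit_from_simulation

# published simulation conditions of the four oscillation archetypes
FIG3 = {
    "3A": dict(model="open", V_PLC=0.1, delta=2.0, C_t=None, t_end=800.0),
    "3B": dict(model="closed", V_PLC=0.1, delta=0.0, C_t=140.0, t_end=200.0),
    "3C": dict(model="closed", V_PLC=0.1, delta=0.0, C_t=75.0, t_end=400.0),
    "3D": dict(model="closed", V_PLC=0.195, delta=0.0, C_t=95.0, t_end=800.0),
}


def fig3_params(panel: str) -> tuple[str, t.Parameters, float]:
    spec = FIG3[panel]
    kw = {} if spec["C_t"] is None else {"C_t": spec["C_t"]}
    return (spec["model"],
            t.Parameters(V_PLC=spec["V_PLC"], delta=spec["delta"], **kw),
            spec["t_end"])


@pytest.fixture(scope="session")
def fig3_runs():
    """Trajectory + features of the four archetype simulations."""
    out = {}
    for panel in FIG3:
        model, params, t_end = fig3_params(panel)
        init = t.unstimulated_equilibrium(model, params).state
        traj = t.integrate(model, params, init, t_end, dt_out=0.005)
        feats = t.extract_features(traj, params)
        out[panel] = (model, params, traj, feats)
    return out


@pytest.fixture(scope="session")
def open_eq_branch():
    """Open-cell equilibrium branch in V_PLC at delta = 2."""
    p = t.Parameters(V_PLC=0.0, delta=2.0)
    start = t.unstimulated_equilibrium("open", p).state
    return continue_equilibria("open", p, "V_PLC", (0.0, 0.3), start)


@pytest.fixture(scope="session")
def open_po_branch():
    """CRAC periodic-orbit branch in V_PLC at delta = 2."""
    p = t.Parameters(V_PLC=0.1, delta=2.0)
    orbit = orbit_from_simulation("open", p, n_nodes=20)
    return continue_periodic_orbits("open", p, "V_PLC", orbit, (0.04, 0.13),
                                    max_steps=90, ds0=2e-2, ds_max=1.5e-1)


@pytest.fixture(scope="session")
def closed_branches():
    """Closed-cell equilibrium + orbit branches for C_t = 140, 95, 75."""
    out = {}
    seeds = {140.0: 0.1, 95.0: 0.09, 75.0: 0.06}
    steps = {140.0: 120, 95.0: 160, 75.0: 220}
    for ct, seed in seeds.items():
        p = t.Parameters(V_PLC=0.0, delta=0.0, C_t=ct)
        eq = continue_equilibria("closed", p, "V_PLC", (0.0, 0.6),
                                 t.unstimulated_equilibrium("closed", p).state)
        orbit = orbit_from_simulation("closed", p.replace(V_PLC=seed),
                                      n_nodes=40, t_transient=300,
                                      t_window=200)
        po = continue_periodic_orbits("closed", p, "V_PLC", orbit, (0.0, 0.6),
                                      max_steps=steps[ct], ds0=2e-2,
                                      ds_max=1.5e-1)
        out[ct] = (eq, po)
    return out


@pytest.fixture(scope="session")
def s1_eq_branch():
    """Equilibrium branch in the CRAC steepness s1 at V_PLC = 0.1."""
    p = t.Parameters(V_PLC=0.1, delta=2.0)
    start = t.stimulated_equilibrium("open", p).state
    return continue_equilibria("open", p, "s1", (0.3, 0.1), start)


@pytest.fixture(scope="session")
def s1_vplc_curve(s1_eq_branch):
    p = t.Parameters(V_PLC=0.1, delta=2.0)
    return continue_hopf_2par("open", p, "s1", "V_PLC",
                              s1_eq_branch.hopf_points()[0],
                              box={"s1": (0.05, 0.6), "V_PLC": (0.005, 0.6)})


@pytest.fixture(scope="session")
def taus_vplc_curve():
    p = t.Parameters(V_PLC=0.1, delta=2.0)
    start = t.stimulated_equilibrium("open", p).state
    br = continue_equilibria("open", p, "tau_s", (15.0, 200.0), start)
    return continue_hopf_2par("open", p, "tau_s", "V_PLC",
                              br.hopf_points()[0],
                              box={"tau_s": (0.5, 300.0), "V_PLC": (0.002, 0.8)})


@pytest.fixture(scope="session")
def delta_vplc_curves():
    """Hopf-curve families in the delta-V_PLC plane at K_e = 800 and 400."""
    box = {"delta": (1e-3, 4.0), "V_PLC": (0.005, 0.6)}
    out = {}
    for Ke in (800.0, 400.0):
        fams = {}
        for delta, fam in ((2.0, "crac"), (0.01, "spike")):
            p = t.Parameters(V_PLC=0.0, delta=delta, K_e=Ke)
            br = continue_equilibria("open", p, "V_PLC", (0.0, 0.6),
                                     t.unstimulated_equilibrium("open", p).state)
            hbs = br.hopf_points()
            fams[fam] = (continue_hopf_2par("open", p, "V_PLC", "delta",
                                            hbs[0], box=box)
                         if hbs else None)
        out[Ke] = fams
    return out


@pytest.fixture(scope="session")
def fig7_runs():
    p = t.Parameters(V_PLC=0.0, delta=2.0)
    return {ce0: t.run_fig7_scenario(ce0, p) for ce0 in (809.0, 850.0)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240613)
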