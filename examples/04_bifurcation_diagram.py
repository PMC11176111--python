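"""One-parameter bifurcation diagrams in the stimulation strength V_PLC.

Open cell (delta=2): the equilibrium destabilizes between two Hopf points
and a branch of stable periodic orbits (the CRAC cycle) spans the window.
Closed cell (C_t=95): the Hopf points are subcritical; the orbit branch
folds at two saddle-nodes of periodic orbits (SNPO) and loses stability
at a period doubling (PD).
"""

import tcellca as t
from tcellca.continuation import continue_equilibria
from tcellca.orbits import continue_periodic_orbits, orbit_from_simulation

# open cell
p = t.Parameters(V_PLC=0.0, delta=2.0)
eq = continue_equilibria("open", p, "V_PLC", (0.0, 0.3),
                         t.unstimulated_equilibrium("open", p).state)
hbs = sorted(h.par_value for h in eq.hopf_points())
print(f"open cell, delta=2: Hopf points at V_PLC = "
      f"{hbs[0]:.4f} and {hbs[1]:.4f}")
orbit = orbit_from_simulation("open", p.replace(V_PLC=0.1), n_nodes=20)
po = continue_periodic_orbits("open", p, "V_PLC", orbit, (0.04, 0.13),
                              max_steps=60, ds0=2e-2, ds_max=1.5e-1)
print(f"  stable periodic branch over V_PLC in "
      f"[{po.par_values.min():.4f}, {po.par_values.max():.4f}], "
      f"period {po.periods.min():.1f}-{po.periods.max():.1f} s")

# closed cell, intermediate total calcium
pc = t.Parameters(V_PLC=0.0, delta=0.0, C_t=95.0)
eqc = continue_equilibria("closed", pc, "V_PLC", (0.0, 0.6),
                          t.unstimulated_equilibrium("closed", pc).state)
orbc = orbit_from_simulation("closed", pc.replace(V_PLC=0.09), n_nodes=40,
                             t_transient=300, t_window=200)
poc = continue_periodic_orbits("closed", pc, "V_PLC", orbc, (0.0, 0.6),
                               max_steps=160, ds0=2e-2, ds_max=1.5e-1)
snpo = sorted(q.par_value for q in poc.detected("SNPO"))
pd = sorted(q.par_value for q in poc.detected("PD"))
print(f"closed cell, C_t=95: Hopf points at "
      f"{', '.join(f'{h.par_value:.4f}' for h in eqc.hopf_points())}")
print(f"  SNPO at V_PLC = {snpo}, PD at V_PLC = {pd}")
print(f"  the orbits are attractors only between SNPO1 ({snpo[0]:.4f}) "
      f"and PD1 ({pd[0]:.4f})")
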