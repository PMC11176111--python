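"""Two-parameter Hopf curves: how steep and how slow must SOCE be?

Continues the Hopf point of the open-cell model in two parameters:
(i) CRAC steepness s1 against stimulation V_PLC — oscillations need a
minimum steepness; (ii) CRAC formation delay tau_s against V_PLC — the
oscillatory region is a closed island, so the delay is bounded above and
below; (iii) delta against V_PLC at a lowered activation midpoint
K_e = 400 µM, where the CRAC-driven and spike-driven oscillatory regions
start to overlap.
"""

import tcellca as t
from tcellca.continuation import continue_equilibria, continue_hopf_2par
from tcellca.regions import region_intersection_delta

p = t.Parameters(V_PLC=0.1, delta=2.0)
start = t.stimulated_equilibrium("open", p).state

# (i) steepness
br = continue_equilibria("open", p, "s1", (0.3, 0.1), start)
hb = br.hopf_points()[0]
curve = continue_hopf_2par("open", p, "s1", "V_PLC", hb,
                           box={"s1": (0.05, 0.6), "V_PLC": (0.005, 0.6)})
print(f"steepness: at V_PLC=0.1 the CRAC branch ends at s1 = "
      f"{hb.par_value:.4f};")
print(f"  over all V_PLC the Hopf curve reaches down to s1 = "
      f"{curve.p1_values.min():.4f} — below that no CRAC oscillation exists")

# (ii) delay
br2 = continue_equilibria("open", p, "tau_s", (15.0, 200.0), start)
curve2 = continue_hopf_2par("open", p, "tau_s", "V_PLC",
                            br2.hopf_points()[0],
                            box={"tau_s": (0.5, 300.0), "V_PLC": (0.002, 0.8)})
print(f"delay: the tau_s-V_PLC Hopf curve is "
      f"{'closed' if curve2.closed else 'open'}; tau_s in "
      f"[{curve2.p1_values.min():.1f}, {curve2.p1_values.max():.1f}] s — "
      f"the CRAC delay must be neither too small nor too large")

# (iii) region intersection at a lowered activation midpoint
box = {"delta": (1e-3, 4.0), "V_PLC": (0.005, 0.6)}
fams = {}
for delta, fam in ((2.0, "crac"), (0.01, "spike")):
    pk = t.Parameters(V_PLC=0.0, delta=delta, K_e=400.0)
    brk = continue_equilibria("open", pk, "V_PLC", (0.0, 0.6),
                              t.unstimulated_equilibrium("open", pk).state)
    fams[fam] = continue_hopf_2par("open", pk, "V_PLC", "delta",
                                   brk.hopf_points()[0], box=box)
d_star = region_intersection_delta(fams["crac"], fams["spike"])
print(f"at K_e=400 µM the two oscillatory regions overlap from delta = "
      f"{d_star:.3f} upward; at the default K_e=800 µM they are disjoint")
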