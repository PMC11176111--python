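"""Anatomy of the CRAC-mediated oscillation.

Reports the store (ER) depletion per cycle, the range of the
store-operated influx variable s, and contrasts the IP₃R open probability
during the slow CRAC cycle with its behaviour during a narrow spike: the
slow cycle keeps the receptor slightly open for a gradual leak, while the
spike opens it briefly but strongly.
"""

import numpy as np

import tcellca as t

# slow CRAC cycle: open cell with store-operated entry
p2 = t.Parameters(V_PLC=0.1, delta=2.0)
traj2 = t.integrate("open", p2, t.unstimulated_equilibrium("open", p2).state,
                    800.0, dt_out=0.01)
f2 = t.extract_features(traj2, p2)

print(f"CRAC cycle: period {f2.period:.1f} s, c in "
      f"[{f2.c_min:.3f}, {f2.c_max:.3f}] µM")
print(f"  ER load cycles between {f2.ce_min:.0f} and {f2.ce_max:.0f} µM "
      f"(depletion {f2.er_depletion_per_cycle:.1f} µM per cycle)")
print(f"  influx s peaks at {100 * f2.s_max_fraction:.0f}% of its maximal "
      f"rate V_SOCE")

# narrow spike: same stimulation without membrane transport, ER at 770 µM
p0 = t.Parameters(V_PLC=0.1, delta=0.0, C_t=140.0)
eq = t.unstimulated_equilibrium("closed", p0)
traj0 = t.integrate("closed", p0, eq.state, 200.0, dt_out=0.002)

half = lambda tr: tr.after(tr.times[0] + 0.5 * (tr.times[-1] - tr.times[0]))
p0_crac = half(traj2).fluxes()["P0"].to_numpy()
p0_spike = half(traj0).fluxes()["P0"].to_numpy()
puls = lambda x: x.max() / np.median(x)
print(f"  IP3R open probability: CRAC cycle max {p0_crac.max():.1e} "
      f"(max/median {puls(p0_crac):.1f}) vs narrow spike max "
      f"{p0_spike.max():.1e} (max/median {puls(p0_spike):.1f})")
print()
print("During the slow CRAC cycle the receptor's open probability stays a")
print("smooth, low wave — a gradual store leak; during the narrow spike it")
print("fires in sharp pulses, the signature of fast Ca²⁺-induced Ca²⁺")
print("release. Suppressing that pulsatility is how CRAC activity silences")
print("the spiking mechanism.")
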