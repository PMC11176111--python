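"""Regime occupancy of the delta-V_PLC plane by direct simulation.

Each grid cell is simulated from its resting state and the waveform is
classified. At the default CRAC midpoint (K_e = 800 µM) the spike-type
and CRAC-type oscillations live in disjoint regions separated by a
quiescent band; at K_e = 400 µM a coexistence band with hybrid
spike-on-CRAC orbits appears between them.
"""

import tcellca as t
from tcellca.regions import region_map

deltas = [0.01, 0.3, 0.62, 1.0, 2.0, 3.0]
vplcs = [0.06, 0.10, 0.15]

for Ke in (800.0, 400.0):
    p = t.Parameters(V_PLC=0.1, delta=2.0, K_e=Ke)
    grid = region_map("open", p, "delta", deltas, "V_PLC", vplcs, t_end=600.0)
    print(f"K_e = {Ke:.0f} µM (rows: delta, columns: V_PLC = {vplcs})")
    for i, d in enumerate(grid.p1_values):
        row = " | ".join(f"{grid.labels[i, j]:18s}" for j in range(len(vplcs)))
        print(f"  delta={d:4.2f}  {row}")
    print()
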