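# Methods

## The model

`tcellca` implements a five-variable ODE model of cytosolic Ca²⁺ handling
in T-lymphocytes in which two oscillatory mechanisms compete: slow cycles
driven by store-operated Ca²⁺ entry (SOCE) through the CRAC channel, and
fast spikes driven by Ca²⁺-induced Ca²⁺ release (CICR) at the IP₃
receptor. The state is (c, c_e, h, p, s): cytosolic and ER Ca²⁺ (µM), the
IP₃R inactivation gate (dimensionless), IP₃ (µM), and the CRAC influx
rate s (µM/s).

    dc/dt   = J_IP3R − J_SERCA + δ (s − J_PM)
    dc_e/dt = γ (J_SERCA − J_IP3R)
    τ_h dh/dt = h_∞(c) − h
    τ_p dp/dt = V_PLC − J_deg(c, p)
    τ_s ds/dt = J_SOCE(c_e) − s

δ scales all plasma-membrane transport relative to ER transport. With
δ = 0 the total free Ca²⁺ C_t = c + c_e/γ is conserved and s decouples,
leaving the three-variable *closed-cell* model in (c, h, p) with
c_e = γ(C_t − c). The closed-cell right-hand side is implemented
independently, with its fluxes written in terms of c and C_t, and is
cross-validated against the open-cell form under substitution (agreement
to 1e-12 is enforced by tests).

Fluxes (all µM/s):

    J_SOCE  = V_SOCE / (1 + exp(s₁ (c_e − K_e)))          store-operated entry
    J_SERCA = V_SERCA (c² − K̄ c_e²) / (c² + K_SERCA²)     bidirectional pump
    J_PM    = V_PM c² / (c² + K_PM²)                       PMCA extrusion
    J_deg   = V_deg c²/(c² + K_deg²) · p                   Ca²⁺-boosted IP₃ decay

IP₃R gating (Hill-type reduction of the two-mode receptor model):

    φ_c = c⁴/(c⁴+K_c⁴)     φ_p = p²/(p²+K_p²)     φ̄_p = K_p²/(p²+K_p²)
    h_∞ = K_h⁴/(K_h⁴+c⁴)   τ_h(c) = τ_max K_τ⁴/(K_τ⁴+c⁴)
    β = φ_p φ_c h          α = φ̄_p (1 − φ_c h_∞)
    P₀ = β/(β + k_β(β+α))  J_IP3R = k_f P₀ (c_e − c)

These ER/PM flux forms follow the established lineage of Ca²⁺ models
this one extends. The transcription was fixed by requiring simultaneous
agreement with the published quantitative anchors of this model: the resting balance
(c, c_e, s) = (0.0809, 809, 0.4219) of the unstimulated open cell, the
~20 µM per-cycle ER depletion of the CRAC cycle with c_e cycling between
~790 and ~820 µM and s peaking near 50% of V_SOCE, and the ~10 s broad
spike period at C_t = 75. Hill-exponent variants (2 instead of 4 in h_∞
or τ_h, 4 instead of 2 in φ_p) each break at least one of these anchors
and were rejected.

Units are µM and seconds throughout; there is no non-dimensionalization.
K_τ is treated as a concentration (µM) since it is compared against c.
K̄ (dimensionless, 1e-8) is the SERCA reverse-mode constant; it sets the
resting ratio c/c_e = √K̄ = 1e-4, which reproduces the published resting
states (c ≈ 0.08 µM at c_e ≈ 800 µM, and the closed-cell loads c_e = 770,
412, 522 µM at C_t = 140, 75, 95). A larger K̄ = 1e-6 is dynamically
impossible: SERCA would run backwards at all physiological c and the
store would drain monotonically.

The default parameter set (bundled as `data/default_parameters.json`) is
the published reference set; the stimulation strength V_PLC and the
transport ratio δ are scenario inputs and must always be given
explicitly. h is never clipped during integration — the dynamics keep it
in [0, 1] when h_∞ is in range, and silent clipping could mask
transcription errors; range checks live in state validation only.

## Numerics

**Kernels.** The right-hand sides, their state Jacobians and the full
parameter-derivative matrices are generated symbolically once
(`tools/generate_kernels.py`, sympy) into `_kernels.py` as plain
scalar-math functions, jitted with numba when available. Tests pin the
kernels against the symbolic forms and against finite differences.

**Integration.** `solve_ivp` with LSODA, analytic Jacobian, rtol 1e-8 /
atol 1e-10, dense uniform output. Runs are deterministic: fixed inputs
give bitwise-identical trajectories.

**Equilibria.** Damped Newton with the analytic Jacobian to residual
1e-10, returning the local eigenvalues. The unstimulated (V_PLC = 0)
state is constructed semi-analytically (p = 0, IP₃R shut, SERCA balance
c = √K̄ c_e, PM balance s = J_SOCE = J_PM) and polished by Newton.
Stimulated equilibria inside oscillatory windows are reached by homotopy
in V_PLC.

**Feature extraction.** Transient discard (default: first half of the
run), period from linear-interpolated upward crossings of c through its
midrange, a second period between principal spikes (prominence ≥ 50% of
the peak-to-trough range) for bursting waveforms, amplitude reported both
as the post-transient peak of c and as peak-to-trough (the source
literature uses both readings). Regime classification is rule-based with
all thresholds exposed (`RegimeThresholds`): quiescent below 1e-3 µM
peak-to-trough; *hybrid* when sharp spikes ride on a slowly modulated
influx (peak-to-trough of s above 10% of V_SOCE); *CRAC-sinusoidal* for
non-spiky waveforms with duty cycle 0.4–0.6 and visible influx;
*plateau* with ≥ 2 secondary maxima per cycle on the elevated phase;
narrow versus wide spikes separate by the absolute spike width near the
base (rel. height 0.8; default boundary 1.6 s). The width criterion
replaces a duty-cycle rule that a naive reading would suggest: the broad
spike of this model is wide at its base but brief at half height, so a
midline duty cycle cannot distinguish it from a narrow spike.

**Equilibrium continuation.** Pseudo-arclength with a secant-free
bordered tangent, component-scaled arclength metric (states by magnitude,
the parameter by its range), adaptive step. Eigenvalues at every accepted
point; Hopf points detected from the unstable-eigenvalue count changing
by two with a complex pair, saddle-nodes from a determinant sign change;
both localized by bisection on the test function to 1e-5 in the
parameter, storing ω and the complex eigenvector at Hopf points. The
machinery accepts any vector field through `systems.CustomSystem`
(missing derivatives by central differences with step 1e-7·(1+|x|)); the
test suite uses an analytically placed Hopf normal form as an exactness
oracle.

**Periodic orbits.** Multiple shooting rather than orthogonal
collocation: the cycle is split into m segments (20 for the smooth
open-cell cycle, 40 for closed-cell spikes) integrated with LSODA at
rtol 1e-10 / atol 1e-12 together with the variational and
parameter-sensitivity equations; the phase is pinned by orthogonality to
the vector field at a reference node. Segment boundaries are placed at
equal increments of normalized state-space arclength, which concentrates
nodes on the fast spike and keeps the segment transition matrices
comparable in magnitude — with equal-time segments the stiff closed-cell
Newton systems become too ill-conditioned to converge below the 1e-8
boundary-value residual that is enforced per orbit. Floquet multipliers
come from the monodromy product over the segments; the trivial
multiplier is within 1e-3 of 1 on every computed orbit.

Branches are continued by pseudo-arclength with a secant tangent in a
scaled metric, a trust-region cap on corrector steps, and a guard
rejecting corrections that fall behind the current point (the branch can
otherwise be retraced on high-curvature stretches). Bifurcation
detection along the branch: SNPO as a parameter fold confirmed by a
nontrivial multiplier at +1 (and, when a branch creeps up to a fold it
cannot round, the endpoint is recorded as the SNPO); PD from a sign
change of Π(µ+1) over the nontrivial multipliers (this catches the
second doubling, where the *smaller* real multiplier crosses −1); TR
from a complex pair crossing the unit circle. PD/TR are refined by
secant re-solves to 1e-4 in the parameter, folds by a local parabola.
Near a Hopf point a second multiplier tends to +1 and the shooting
system degenerates; branches stop there on vanishing amplitude (4e-3 µM)
or on stalled parameter progress, and small emanating orbits are instead
obtained directly from `orbit_from_hopf`, which pins the amplitude on
the linearized eigenplane and solves with the parameter free (its period
reproduces 2π/ω to well under 2% at amplitude 1e-3).

**Codim-2 Hopf curves.** The extended defining system — equilibrium,
J v = iω v for v = v_r + i v_i, and two normalization rows pinning the
eigenvector against a fixed reference vector — is continued by
pseudo-arclength in (p1, p2) with finite-difference Jacobians of the
(3n+3)-dimensional system. Curves terminate at a user box or close on
themselves (detected by returning to the start); closure is how the
bounded delay window in the τ_s–V_PLC plane is established.

**Region maps and intersections.** `region_map` simulates every cell of
a parameter grid from its own resting state and classifies the waveform.
The δ at which the CRAC-driven and spike-driven oscillatory regions
first overlap is computed from the two Hopf-curve families in the
(δ, V_PLC) plane: the CRAC region lies above its curve's lower envelope
δ_lo(V_PLC), the spike region below its upper envelope δ_hi(V_PLC), and
the first contact is min δ_lo over the window where δ_lo ≤ δ_hi.

## Problem sizes and defaults

Simulations use horizons of 200–1000 s (≥ 20 cycles of the slowest
attractor) at 2–10 ms output spacing; orbit branches use up to ~150–250
accepted orbits per diagram; codim-2 curves a few hundred points; regime
grids stay at or below ~20×10 cells. These sizes keep every analysis in
the minutes range on one core while meeting the stated numerical
tolerances.

## Known limitations and open edges

* The fold at the low-V_PLC end of the C_t = 75 orbit branch is reached
  by creeping rather than rounded, so its location carries the endpoint
  accuracy (~1e-4 in V_PLC) rather than a fold-refined one.
* At C_t = 75 the period-doubling test function crosses zero four times
  on the primary branch (a close pair near V_PLC ≈ 0.125 reflecting a
  brief complex-multiplier excursion); the first crossing is the one
  that terminates the stable segment.
* The isolated plateau-spike branch is located by simulation and
  continued locally; no connection to the primary branch is attempted,
  and no torus bifurcation was found on the slice examined — the
  region-III boundary in the two-parameter set is therefore reported
  from the points actually detected, which may exclude a TR curve.
* With the bundled defaults the printed hybrid-orbit parameter point
  (K_e = 400, δ = 0.62, V_PLC = 0.1) yields a plain spike train; hybrid
  spike-on-CRAC orbits appear at δ ≈ 0.8–1.2 under the same K_e. The
  hybrid's published parameter table is not part of the reference set,
  so the defaults evidently differ from it.
* The waveform classifier is tuned to this model's attractors; its
  thresholds are physical quantities (widths in seconds, fractions of
  V_SOCE) but they have not been validated against experimental traces,
  and passing tests say nothing about fluorescence data with noise,
  drift, or run-down.
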