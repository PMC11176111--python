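"""Time integration, equilibria and the ER-load stimulation scenario."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model as _m
from ._jacobian import jacobian
from .parameters import Parameters

__all__ = [
    "Trajectory", "IntegrationError", "integrate", "EquilibriumResult",
    "find_equilibrium", "unstimulated_equilibrium",
    "unstimulated_partial_equilibrium", "run_fig7_scenario", "TransientReport",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time t={t_last:.6g} s)")
        self.t_last = t_last


@dataclass
class Trajectory:
    """Time-stamped solution of one model run.

    ``states`` has shape (n_vars, n_times) with rows ordered as the model's
    state vector: (c, c_e, h, p, s) for the open cell, (c, h, p) for the
    closed cell.
    """

    times: np.ndarray
    states: np.ndarray
    model: str
    params: Parameters

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states")

    @property
    def var_names(self) -> tuple[str, ...]:
        return _m.OPEN_VARS if self.model == "open" else _m.CLOSED_VARS

    @property
    def c(self) -> np.ndarray:
        return self.states[0]

    @property
    def c_e(self) -> np.ndarray:
        if self.model == "open":
            return self.states[1]
        return self.params.gamma * (self.params.C_t - self.states[0])

    @property
    def h(self) -> np.ndarray:
        return self.states[2] if self.model == "open" else self.states[1]

    @property
    def p(self) -> np.ndarray:
        return self.states[3] if self.model == "open" else self.states[2]

    @property
    def s(self) -> Optional[np.ndarray]:
        return self.states[4] if self.model == "open" else None

    def total_calcium(self) -> np.ndarray:
        """C_t(t) = c + c_e/γ (conserved when delta = 0)."""
        return self.c + self.c_e / self.params.gamma

    def fluxes(self) -> pd.DataFrame:
        """Flux/probability traces aligned to ``times``."""
        rows = [_m.er_fluxes(self.states[:, i], self.params, model=self.model).as_dict()
                for i in range(self.times.size)]
        return pd.DataFrame(rows, index=pd.Index(self.times, name="t"))

    def after(self, t0: float) -> "Trajectory":
        """The part of the trajectory with t >= t0."""
        i = int(np.searchsorted(self.times, t0))
        i = min(i, self.times.size - 2)
        return Trajectory(self.times[i:], self.states[:, i:], self.model, self.params)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states.T, columns=list(self.var_names))
        df.insert(0, "t", self.times)
        if self.model == "closed":
            df["c_e"] = self.c_e
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate(model: str, params: Parameters, init, t_end: float,
              dt_out: float = 0.01, *, t_start: float = 0.0,
              rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA", max_step: float = 1.0) -> Trajectory:
    """Integrate a model with a stiff-capable adaptive solver.

    ``init`` may be a state object or a raw array. The solution is sampled
    on a uniform grid with spacing ``dt_out``. The run is deterministic:
    identical inputs give identical output.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if isinstance(init, (_m.OpenState, _m.ClosedState)):
        y0 = init.as_array()
    else:
        y0 = np.asarray(init, dtype=float)
    if y0.size != _m.n_vars(model):
        raise ValueError(f"initial state has {y0.size} entries; "
                         f"{model} model needs {_m.n_vars(model)}")
    if not np.all(np.isfinite(y0)):
        raise ValueError("non-finite initial state")
    t_eval = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    from ._kernels import jac_closed, jac_open, rhs_closed, rhs_open
    f_k = rhs_open if model == "open" else rhs_closed
    j_k = jac_open if model == "open" else jac_closed
    pv = params.vector
    use_jac = method in ("LSODA", "BDF", "Radau")
    sol = solve_ivp(lambda t, y: f_k(y, pv), (t_start, t_end), y0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval,
                    jac=(lambda t, y: j_k(y, pv)) if use_jac else None,
                    max_step=max_step)
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t_start
        raise IntegrationError(sol.message, float(t_last))
    return Trajectory(sol.t, sol.y, model, params)


@dataclass
class EquilibriumResult:
    """Equilibrium state with its local linearization."""

    state: np.ndarray
    eigenvalues: np.ndarray
    model: str
    params: Parameters
    residual: float = 0.0

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    def as_state(self):
        cls = _m.OpenState if self.model == "open" else _m.ClosedState
        return cls.from_array(self.state)


def find_equilibrium(model: str, params: Parameters, guess,
                     tol: float = 1e-11, max_iter: int = 50) -> EquilibriumResult:
    """Damped Newton solve of rhs = 0 from ``guess``.

    Returns the equilibrium together with the eigenvalues of the Jacobian
    there. Raises ``RuntimeError`` on non-convergence.
    """
    from .systems import resolve
    ops = resolve(model)
    if isinstance(guess, (_m.OpenState, _m.ClosedState)):
        y = guess.as_array()
    else:
        y = np.array(guess, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite guess")
    r = ops.rhs(y, params)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            break
        J = ops.jac(y, params)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        lam = 1.0
        for _damp in range(30):
            y_new = y + lam * step
            try:
                r_new = ops.rhs(y_new, params)
            except ValueError:
                r_new = None
            if r_new is not None and np.all(np.isfinite(r_new)) and \
                    np.max(np.abs(r_new)) < np.max(np.abs(r)):
                y, r = y_new, r_new
                break
            lam *= 0.5
        else:
            raise RuntimeError("Newton damping failed to reduce the residual")
    else:
        raise RuntimeError(f"Newton did not converge in {max_iter} iterations "
                           f"(residual {np.max(np.abs(r)):.3g})")
    eig = np.linalg.eigvals(ops.jac(y, params))
    return EquilibriumResult(y, eig, model, params, residual=float(np.max(np.abs(r))))


def unstimulated_equilibrium(model: str, params: Parameters) -> EquilibriumResult:
    """Equilibrium of the unstimulated cell (V_PLC = 0).

    With V_PLC = 0 the IP₃ level relaxes to p = 0, the IP₃R is closed, and
    the resting state follows from SERCA balance (c = √K̄ · c_e) plus, in
    the open cell, the PM balance s = J_SOCE(c_e) = J_PM(c).
    """
    p0 = params.replace(V_PLC=0.0)
    root_kbar = np.sqrt(params.K_bar)
    if model == "open":
        def g(c_e):
            c = root_kbar * c_e
            return _m.j_soce(c_e, p0) - _m.j_pm(c, p0)
        c_e = brentq(g, 1e-3, 10 * params.K_e, xtol=1e-12)
        c = root_kbar * c_e
        _, h_inf, _ = _m.ip3r_gating(c, 0.0, 0.0, p0)
        guess = np.array([c, c_e, h_inf, 0.0, float(_m.j_soce(c_e, p0))])
    else:
        c = brentq(lambda cv: cv - root_kbar * params.gamma * (params.C_t - cv),
                   0.0, params.C_t, xtol=1e-14)
        _, h_inf, _ = _m.ip3r_gating(c, 0.0, 0.0, p0)
        guess = np.array([c, h_inf, 0.0])
    return find_equilibrium(model, p0, guess)


def stimulated_equilibrium(model: str, params: Parameters,
                           n_steps: int = 25) -> EquilibriumResult:
    """Equilibrium at the given V_PLC, reached by homotopy from V_PLC = 0.

    Newton alone may not converge from the resting state when the target
    equilibrium is far (or unstable, inside a Hopf region); stepping V_PLC
    up gradually keeps every solve in its basin.
    """
    eq = unstimulated_equilibrium(model, params)
    target = params.V_PLC
    state = eq.state
    for v in np.linspace(0.0, target, n_steps + 1)[1:]:
        eq = find_equilibrium(model, params.replace(V_PLC=float(v)), state)
        state = eq.state
    return eq


def unstimulated_partial_equilibrium(c_e: float, params: Parameters) -> tuple[float, float]:
    """Resting (c, s) consistent with a prescribed ER load c_e.

    Solves the ER balance J_SERCA = J_IP3R (with V_PLC = 0, hence p = 0 and
    h = h_∞(c)) for c at the given c_e, and the CRAC balance s = J_SOCE(c_e).
    Used to build initial conditions for stimulation protocols that start
    from a partly loaded or overloaded store.
    """
    if not np.isfinite(c_e) or c_e <= 0:
        raise ValueError("c_e must be positive")
    p0 = params.replace(V_PLC=0.0)

    def g(c):
        _, h_inf, _ = _m.ip3r_gating(c, 0.0, 0.0, p0)
        return float(_m.j_serca(c, c_e, p0) - _m.j_ip3r(c, c_e, h_inf, 0.0, p0))

    hi = max(1.0, 2.0 * np.sqrt(params.K_bar) * c_e)
    if g(0.0) * g(hi) > 0:
        raise ValueError("no ER-balance root in the search bracket")
    c = brentq(g, 0.0, hi, xtol=1e-14)
    s = float(_m.j_soce(c_e, params))
    return float(c), s


@dataclass
class TransientReport:
    """Transient spiking before convergence to the CRAC limit cycle."""

    n_spikes: int
    duration: float
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))
    cycle_period: float = float("nan")
    cycle_c_max: float = float("nan")


def run_fig7_scenario(c_e_init: float, params: Parameters, *,
                      t_end: float = 600.0, dt_out: float = 0.01,
                      V_PLC_on: float = 0.1) -> tuple[Trajectory, TransientReport]:
    """Stimulate an open cell from a prescribed initial ER load.

    The initial (c, s) come from the unstimulated balance at ``c_e_init``;
    h starts on its resting curve and p at zero. At t = 0 the stimulation
    V_PLC steps from 0 to ``V_PLC_on``. Overloaded stores (c_e above the
    CRAC midpoint, so s ≈ 0 initially) produce a burst of transient narrow
    spikes until the CRAC channel forms and the slow cycle takes over.
    """
    from .features import extract_features, count_transient_spikes

    c0, s0 = unstimulated_partial_equilibrium(c_e_init, params)
    _, h_inf, _ = _m.ip3r_gating(c0, 0.0, 0.0, params)
    init = np.array([c0, c_e_init, h_inf, 0.0, s0])
    run_params = params.replace(V_PLC=V_PLC_on)
    traj = integrate("open", run_params, init, t_end, dt_out)
    feats = extract_features(traj, run_params)
    n_spikes, duration, spike_times = count_transient_spikes(traj, feats)
    report = TransientReport(n_spikes=n_spikes, duration=duration,
                             spike_times=spike_times,
                             cycle_period=feats.period,
                             cycle_c_max=feats.c_max)
    return traj, report
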