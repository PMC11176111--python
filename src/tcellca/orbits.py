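"""Periodic-orbit continuation with Floquet stability.

Orbits are solved as periodic boundary-value problems by multiple
shooting: the cycle is split into m equal-time segments, each integrated
with a stiff-capable adaptive solver together with its variational
(monodromy) and parameter-sensitivity equations. The phase is pinned by
orthogonality to the vector field at a reference point. Branches are
traced by pseudo-arclength continuation in one parameter; Floquet
multipliers come from the monodromy product over the segments and drive
the detection of saddle-nodes of periodic orbits (SNPO, a fold in the
parameter), period doublings (PD, a real multiplier through −1) and torus
bifurcations (TR, a complex pair crossing the unit circle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model as _m
from .continuation import BranchPoint
from .parameters import Parameters
from .systems import make_rhs_var, resolve

__all__ = ["PeriodicOrbit", "PeriodicOrbitBranch", "OrbitPoint",
           "solve_orbit", "orbit_from_simulation", "orbit_from_hopf",
           "continue_periodic_orbits", "floquet_multipliers"]

_TRIVIAL_TOL = 1e-3


class OrbitError(RuntimeError):
    pass


def _segment(model: str, params: Parameters, x0: np.ndarray, dt: float,
             par_name: Optional[str], rtol: float, atol: float):
    """Flow, transition matrix and parameter sensitivity over one segment.

    The state is integrated together with its variational (monodromy)
    matrix and, when ``par_name`` is given, the parameter-sensitivity
    vector.
    """
    from .parameters import PARAM_ORDER
    ops = resolve(model)
    n = x0.size
    with_par = par_name is not None
    if ops.rhs_var is not None:
        ip = PARAM_ORDER.index(par_name) if with_par else 0
        pv = params.vector
        kern = ops.rhs_var
        fun = lambda t, z: kern(z, pv, ip)
    else:
        generic = make_rhs_var(ops)
        fun = lambda t, z: generic(z, params, par_name)
    z0 = np.concatenate([x0, np.eye(n).ravel()] +
                        ([np.zeros(n)] if with_par else []))
    sol = solve_ivp(fun, (0.0, dt), z0,
                    method="LSODA", rtol=rtol, atol=atol,
                    dense_output=False)
    if not sol.success:
        raise OrbitError(f"segment integration failed: {sol.message}")
    zT = sol.y[:, -1]
    xT = zT[:n]
    Phi = zT[n:n + n * n].reshape(n, n)
    psi = zT[n + n * n:] if with_par else None
    return xT, Phi, psi


@dataclass
class PeriodicOrbit:
    """A converged periodic orbit at one parameter value.

    ``taus`` holds the (fixed) fractional start times of the shooting
    segments; non-uniform spacing concentrates nodes around fast spikes,
    which keeps the segment transition matrices comparable in size.
    """

    model: str
    params: Parameters
    nodes: np.ndarray          # (m, n) multiple-shooting nodes over one period
    period: float
    multipliers: np.ndarray    # Floquet multipliers incl. the trivial one
    residual: float
    taus: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.taus is None:
            m = self.nodes.shape[0]
            self.taus = np.arange(m) / m

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def trivial_multiplier(self) -> complex:
        return self.multipliers[int(np.argmin(np.abs(self.multipliers - 1.0)))]

    @property
    def nontrivial_multipliers(self) -> np.ndarray:
        i = int(np.argmin(np.abs(self.multipliers - 1.0)))
        return np.delete(self.multipliers, i)

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(self.nontrivial_multipliers) < 1.0 + _TRIVIAL_TOL))

    def c_extrema(self) -> tuple[float, float]:
        traj = self.sample(400)
        return float(traj[:, 0].min()), float(traj[:, 0].max())

    def sample(self, n_samples: int = 400) -> np.ndarray:
        """Dense sampling of the orbit over one period, shape (n_samples, n)."""
        from ._kernels import rhs_closed, rhs_open
        f_k = rhs_open if self.model == "open" else rhs_closed
        pv = self.params.vector
        ts = np.linspace(0.0, self.period, n_samples, endpoint=False)
        sol = solve_ivp(lambda t, y: f_k(y, pv), (0.0, self.period),
                        self.nodes[0], method="LSODA",
                        rtol=1e-10, atol=1e-12, t_eval=ts)
        return sol.y.T


def _fracs(taus: np.ndarray) -> np.ndarray:
    return np.diff(np.r_[taus, 1.0 + taus[0]])


def _assemble(model, params, nodes, T, par_name, rtol, atol, taus=None):
    """Residuals, segment matrices and T/parameter derivative columns."""
    m, n = nodes.shape
    fr = _fracs(taus) if taus is not None else np.full(m, 1.0 / m)
    r = np.empty((m, n))
    Phis = np.empty((m, n, n))
    psis = np.empty((m, n)) if par_name else None
    dT = np.empty((m, n))
    for i in range(m):
        xT, Phi, psi = _segment(model, params, nodes[i], fr[i] * T,
                                par_name, rtol, atol)
        r[i] = xT - nodes[(i + 1) % m]
        Phis[i] = Phi
        dT[i] = resolve(model).rhs(xT, params) * fr[i]
        if par_name:
            psis[i] = psi
    return r, Phis, dT, psis


def solve_orbit(model: str, params: Parameters, nodes: np.ndarray, T: float,
                *, phase_ref: Optional[tuple[np.ndarray, np.ndarray]] = None,
                taus: Optional[np.ndarray] = None,
                rtol: float = 1e-10, atol: float = 1e-12,
                tol: float = 1e-9, max_iter: int = 16) -> PeriodicOrbit:
    """Newton solve of the multiple-shooting system at a fixed parameter.

    Unknowns are the m shooting nodes and the period; the phase condition
    keeps node 0 on the hyperplane through ``phase_ref`` (default: the
    initial node) orthogonal to the vector field there. Newton steps are
    capped in a relative metric, which keeps the iteration stable on stiff
    spiking orbits.
    """
    nodes = np.array(nodes, dtype=float)
    m, n = nodes.shape
    if phase_ref is None:
        x_ref = nodes[0].copy()
        f_ref = resolve(model).rhs(x_ref, params)
    else:
        x_ref, f_ref = phase_ref
    f_ref = f_ref / max(np.linalg.norm(f_ref), 1e-12)
    N = m * n + 1
    for it in range(max_iter):
        r, Phis, dT, _ = _assemble(model, params, nodes, T, None, rtol, atol,
                                   taus)
        phase = f_ref @ (nodes[0] - x_ref)
        res = np.r_[r.ravel(), phase]
        if np.max(np.abs(res)) < tol:
            M = _monodromy(Phis)
            return PeriodicOrbit(model, params, nodes, float(T),
                                 np.linalg.eigvals(M),
                                 float(np.max(np.abs(res))), taus=taus)
        A = np.zeros((N, N))
        for i in range(m):
            A[i * n:(i + 1) * n, i * n:(i + 1) * n] = Phis[i]
            j = ((i + 1) % m) * n
            A[i * n:(i + 1) * n, j:j + n] -= np.eye(n)
            A[i * n:(i + 1) * n, m * n] = dT[i]
        A[m * n, :n] = f_ref
        du = np.linalg.solve(A, -res)
        scale = np.r_[np.maximum(np.abs(nodes.ravel()), 1e-2),
                      max(abs(T), 1.0)]
        dn = np.max(np.abs(du) / scale)
        if dn > 0.5:
            du *= 0.5 / dn
        nodes = nodes + du[:m * n].reshape(m, n)
        T = T + du[m * n]
        if T <= 0 or not np.all(np.isfinite(nodes)):
            raise OrbitError("orbit Newton left the admissible region")
    raise OrbitError(f"orbit Newton did not converge "
                     f"(residual {np.max(np.abs(res)):.3g})")


def _monodromy(Phis: np.ndarray) -> np.ndarray:
    M = Phis[0]
    for i in range(1, Phis.shape[0]):
        M = Phis[i] @ M
    return M


def floquet_multipliers(orbit: PeriodicOrbit) -> np.ndarray:
    return orbit.multipliers


def orbit_from_simulation(model: str, params: Parameters, init=None, *,
                          t_transient: float = 500.0, n_nodes: int = 30,
                          t_window: float = 400.0,
                          rtol: float = 1e-10, atol: float = 1e-12) -> PeriodicOrbit:
    """Locate a stable cycle by integration and converge it by shooting.

    Integrates past the transient, estimates the period from midline
    crossings of c, samples the shooting nodes over one cycle and polishes
    with Newton.
    """
    from .features import extract_features
    from .simulate import integrate, unstimulated_equilibrium

    if init is None:
        init = unstimulated_equilibrium(model, params).state
    warm = integrate(model, params, init, t_transient, dt_out=0.5)
    traj = integrate(model, params, warm.states[:, -1], t_window,
                     dt_out=0.002)
    feats = extract_features(traj, params, transient_fraction=0.0)
    if not feats.oscillating or not np.isfinite(feats.period_principal):
        raise OrbitError("no oscillation found at these parameters")
    T0 = feats.period_principal
    post = traj.after(traj.times[-1] - 3.0 * T0)
    c = post.c
    mid = 0.5 * (c.min() + c.max())
    up = np.where((c[:-1] < mid) & (c[1:] >= mid))[0]
    if up.size == 0:
        raise OrbitError("could not anchor a cycle start")
    i0 = up[0]
    t0 = post.times[i0]
    i1 = int(np.searchsorted(post.times, t0 + T0))
    i1 = min(i1, post.times.size - 1)
    cyc = post.states[:, i0:i1]
    # distribute shooting nodes uniformly in (normalized) arclength so
    # that fast spikes get as many nodes as slow stretches
    span = np.maximum(np.ptp(cyc, axis=1), 1e-12)[:, None]
    speed = np.linalg.norm(np.diff(cyc / span, axis=1), axis=0)
    arc = np.r_[0.0, np.cumsum(speed)]
    arc /= arc[-1]
    targets = np.arange(n_nodes) / n_nodes
    idx = np.searchsorted(arc, targets)
    idx = np.unique(np.clip(idx, 0, cyc.shape[1] - 1))
    while idx.size < n_nodes:   # guard against duplicate quantiles
        extra = np.setdiff1d(np.arange(cyc.shape[1]), idx)[:n_nodes - idx.size]
        idx = np.unique(np.r_[idx, extra])
    nodes = cyc[:, idx].T
    taus = (post.times[i0 + idx] - t0) / T0
    taus = taus - taus[0]
    return solve_orbit(model, params, nodes, T0, taus=taus,
                       rtol=rtol, atol=atol)


def orbit_from_hopf(model: str, params: Parameters, hb: BranchPoint,
                    amplitude: float = 1e-3, n_nodes: int = 20,
                    rtol: float = 1e-10, atol: float = 1e-12) -> PeriodicOrbit:
    """Small orbit emanating from a Hopf point, seeded on the eigenplane.

    The orbit is solved with the bifurcation parameter free and the
    amplitude pinned, so the solution sits on the emanating branch at the
    prescribed (small) amplitude; its period converges to 2π/ω as the
    amplitude goes to zero.
    """
    if hb.eigenvector is None or not np.isfinite(hb.omega):
        raise ValueError("Hopf point carries no eigenpair")
    n = hb.state.size
    m = n_nodes
    v = hb.eigenvector
    vr, vi = np.real(v), np.imag(v)
    nr = np.linalg.norm(vr)
    vr, vi = vr / nr, vi / nr
    omega = abs(hb.omega)
    T0 = 2.0 * np.pi / omega
    theta = 2.0 * np.pi * np.arange(m) / m
    nodes = hb.state[None, :] + amplitude * (np.cos(theta)[:, None] * vr[None, :]
                                             - np.sin(theta)[:, None] * vi[None, :])
    par_name = hb.par_name
    par0 = hb.par_value
    e_amp = vr / np.linalg.norm(vr)

    nodes = np.array(nodes)
    T = T0
    pv = par0
    x_ref = nodes[0].copy()
    N = m * n + 2
    res = None
    for it in range(20):
        p = params.replace(**{par_name: float(pv)})
        f_ref = resolve(model).rhs(x_ref, p)
        r, Phis, dT, psis = _assemble(model, p, nodes, T, par_name, rtol, atol)
        phase = f_ref @ (nodes[0] - x_ref)
        amp = e_amp @ (nodes[0] - hb.state) - amplitude
        res = np.r_[r.ravel(), phase, amp]
        if np.max(np.abs(res)) < 1e-9:
            M = _monodromy(Phis)
            return PeriodicOrbit(model, p, nodes, float(T),
                                 np.linalg.eigvals(M), float(np.max(np.abs(res))))
        A = np.zeros((N, N))
        for i in range(m):
            A[i * n:(i + 1) * n, i * n:(i + 1) * n] = Phis[i]
            j = ((i + 1) % m) * n
            A[i * n:(i + 1) * n, j:j + n] -= np.eye(n)
            A[i * n:(i + 1) * n, m * n] = dT[i]
            A[i * n:(i + 1) * n, m * n + 1] = psis[i]
        A[m * n, :n] = f_ref
        A[m * n + 1, :n] = e_amp
        du = np.linalg.solve(A, -res)
        nodes = nodes + du[:m * n].reshape(m, n)
        T = T + du[m * n]
        pv = pv + du[m * n + 1]
        if T <= 0 or not np.all(np.isfinite(nodes)):
            raise OrbitError("Hopf seeding diverged")
    raise OrbitError(f"Hopf-seeded orbit did not converge "
                     f"(residual {np.max(np.abs(res)):.3g})")


@dataclass
class OrbitPoint:
    """A detected bifurcation on a periodic-orbit branch."""

    kind: str           # "SNPO" | "PD" | "TR"
    par_value: float
    period: float
    index: int
    multiplier: complex = 0.0 + 0.0j


@dataclass
class PeriodicOrbitBranch:
    """A branch of periodic orbits traced in one parameter."""

    model: str
    params: Parameters
    par_name: str
    par_values: np.ndarray
    orbits: list[PeriodicOrbit]
    points: list[OrbitPoint] = field(default_factory=list)
    truncated: bool = False
    period_blowup: bool = False

    @property
    def periods(self) -> np.ndarray:
        return np.array([o.period for o in self.orbits])

    @property
    def stable(self) -> np.ndarray:
        return np.array([o.stable for o in self.orbits])

    def detected(self, kind: str) -> list[OrbitPoint]:
        return [p for p in self.points if p.kind == kind]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pv, o in zip(self.par_values, self.orbits):
            cmin, cmax = o.nodes[:, 0].min(), o.nodes[:, 0].max()
            mu = o.nontrivial_multipliers
            lead = mu[int(np.argmax(np.abs(mu)))] if mu.size else np.nan
            rows.append({self.par_name: pv, "period": o.period,
                         "c_min": cmin, "c_max": cmax,
                         "leading_multiplier_abs": np.abs(lead),
                         "stable": o.stable, "residual": o.residual})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def continue_periodic_orbits(model: str, params: Parameters, par_name: str,
                             start, par_range: tuple[float, float], *,
                             ds0: float = 5e-3, ds_max: float = 4e-2,
                             max_steps: int = 200, n_nodes: int = 30,
                             rtol: float = 1e-10, atol: float = 1e-12,
                             both_directions: bool = True,
                             max_period: float = 1e3,
                             amp_stop: float = 4e-3,
                             loc_tol: float = 1e-4) -> PeriodicOrbitBranch:
    """Trace a branch of periodic orbits by pseudo-arclength continuation.

    ``start`` is either a converged :class:`PeriodicOrbit` (e.g. from
    simulation) or a Hopf :class:`BranchPoint`, in which case the branch is
    seeded from the linearized eigenplane. SNPO, PD and TR bifurcations are
    detected along the way and localized to ``loc_tol`` in the parameter.
    """
    if isinstance(start, BranchPoint):
        orbit0 = orbit_from_hopf(model, params, start, n_nodes=n_nodes,
                                 rtol=rtol, atol=atol)
        pv0 = float(getattr(orbit0.params, par_name))
    else:
        orbit0 = start
        pv0 = float(getattr(orbit0.params, par_name))
    lo, hi = float(min(par_range)), float(max(par_range))
    m, n = orbit0.nodes.shape
    taus = orbit0.taus

    def pack(o, pv):
        return np.r_[o.nodes.ravel(), o.period, pv]

    def correct(u_pred, t_vec, scale, phase_ref):
        """Arclength-constrained Newton around the prediction."""
        u = u_pred.copy()
        x_ref, f_ref = phase_ref
        last = None
        for _ in range(10):
            nodes = u[:m * n].reshape(m, n)
            T, pv = u[m * n], u[m * n + 1]
            if T <= 0 or not np.all(np.isfinite(u)):
                return None
            p = params.replace(**{par_name: float(pv)})
            try:
                r, Phis, dT, psis = _assemble(model, p, nodes, T, par_name,
                                              rtol, atol, taus)
            except (OrbitError, ValueError):
                return None
            phase = f_ref @ (nodes[0] - x_ref)
            arc = t_vec @ ((u - u_pred) / scale)
            res = np.r_[r.ravel(), phase, arc]
            if np.max(np.abs(res[:-1])) < 1e-9 and abs(res[-1]) < 1e-9:
                M = _monodromy(Phis)
                return (PeriodicOrbit(model, p, nodes, float(T),
                                      np.linalg.eigvals(M),
                                      float(np.max(np.abs(res[:-1]))),
                                      taus=taus), pv)
            N = m * n + 2
            A = np.zeros((N, N))
            for i in range(m):
                A[i * n:(i + 1) * n, i * n:(i + 1) * n] = Phis[i]
                j = ((i + 1) % m) * n
                A[i * n:(i + 1) * n, j:j + n] -= np.eye(n)
                A[i * n:(i + 1) * n, m * n] = dT[i]
                A[i * n:(i + 1) * n, m * n + 1] = psis[i]
            A[m * n, :n] = f_ref
            A[m * n + 1, :] = t_vec / scale
            try:
                du = np.linalg.solve(A, -res)
            except np.linalg.LinAlgError:
                return None
            # trust-region cap in the scaled metric
            dn = np.linalg.norm(du / scale)
            if dn > 1.0:
                du *= 1.0 / dn
            u = u + du
            last = res
        return None

    # scale vector: state components O(their magnitude), period O(T), par O(range)
    def make_scale(u):
        s = np.maximum(np.abs(u), 1e-2)
        s[m * n] = max(abs(u[m * n]), 1.0)
        s[m * n + 1] = max(hi - lo, 1e-3)
        return s

    pars = [pv0]
    orbits = [orbit0]
    points: list[OrbitPoint] = []
    truncated = False
    blowup = False

    def trace(direction):
        nonlocal truncated, blowup
        u_prev = pack(orbits[0], pars[0])
        scale = make_scale(u_prev)
        # first step: natural continuation in the parameter
        dpar = direction * max(1e-4, 0.02 * (hi - lo) * ds0 / ds_max)
        seeded = None
        for _ in range(8):
            pv1 = pars[0] + dpar
            p1 = params.replace(**{par_name: float(pv1)})
            try:
                o1 = solve_orbit(model, p1, orbits[0].nodes, orbits[0].period,
                                 phase_ref=(orbits[0].nodes[0],
                                            resolve(model).rhs(
                                                orbits[0].nodes[0],
                                                orbits[0].params)),
                                 taus=taus, rtol=rtol, atol=atol)
                seeded = (o1, pv1)
                break
            except (OrbitError, np.linalg.LinAlgError):
                dpar *= 0.5
        if seeded is None:
            truncated = True
            return [], []
        o1, pv1 = seeded
        out_p, out_o = [pv1], [o1]
        u_cur = pack(o1, pv1)
        ds = ds0
        fails = 0
        stall = 0
        while len(out_p) < max_steps:
            # secant tangent in scaled coordinates
            t_vec = (u_cur - u_prev) / scale
            norm = np.linalg.norm(t_vec)
            if norm < 1e-14:
                break
            t_vec = t_vec / norm
            u_pred = u_cur + ds * t_vec * scale
            f_ref0 = resolve(model).rhs(
                u_cur[:n], params.replace(**{par_name: float(u_cur[-1])}))
            phase_ref = (u_cur[:n], f_ref0 / max(np.linalg.norm(f_ref0), 1e-12))
            got = correct(u_pred, t_vec, scale, phase_ref)
            if got is not None:
                # reject solutions that fall behind the current point
                # (possible on high-curvature stretches of the branch)
                o_try, pv_try = got
                u_try = pack(o_try, pv_try)
                if t_vec @ ((u_try - u_cur) / scale) <= 0:
                    got = None
            if got is None:
                ds *= 0.5
                fails += 1
                if ds < 1e-6 or fails > 25:
                    truncated = True
                    break
                continue
            fails = 0
            o_new, pv_new = got
            out_p.append(pv_new)
            out_o.append(o_new)
            u_prev, u_cur = u_cur, pack(o_new, pv_new)
            scale = make_scale(u_cur)
            ds = min(ds * 1.25, ds_max)
            if not (lo - 1e-9 <= pv_new <= hi + 1e-9):
                break
            if o_new.period > max_period:
                blowup = True
                break
            # vanishing amplitude: the branch has shrunk into a Hopf point
            if np.ptp(o_new.nodes[:, 0]) < amp_stop:
                break
            # near a Hopf the shooting system degenerates (a second
            # multiplier tends to +1) and steps collapse; give up once
            # parameter progress has effectively stopped there
            mu = o_new.nontrivial_multipliers
            near_one = mu.size and np.min(np.abs(mu - 1.0)) < 0.2
            if abs(out_p[-1] - out_p[-2]) < 5e-4 and near_one \
                    and np.ptp(o_new.nodes[:, 0]) < 0.5 * np.ptp(out_o[0].nodes[:, 0]):
                stall += 1
                if stall > 12:
                    break
            else:
                stall = 0
        return out_p, out_o

    p_f, o_f = trace(+1.0)
    if both_directions:
        p_b, o_b = trace(-1.0)
    else:
        p_b, o_b = [], []
    all_p = list(reversed(p_b)) + [pv0] + p_f
    all_o = list(reversed(o_b)) + [orbit0] + o_f

    branch = PeriodicOrbitBranch(model=model, params=params, par_name=par_name,
                                 par_values=np.array(all_p), orbits=all_o,
                                 truncated=truncated, period_blowup=blowup)
    _detect_orbit_bifurcations(branch, loc_tol, par_range=(lo, hi))
    return branch


def _pd_test(o: PeriodicOrbit) -> float:
    """Period-doubling test function Π(µ+1) over nontrivial multipliers.

    Changes sign exactly when a real multiplier crosses −1; complex pairs
    contribute a positive factor |µ+1|².
    """
    mu = o.nontrivial_multipliers
    if mu.size == 0:
        return float("nan")
    g = float(np.real(np.prod(mu + 1.0)))
    # compress the huge dynamic range of spiking-orbit multipliers while
    # keeping the sign
    return float(np.sign(g) * np.log1p(abs(g)))


def _tr_test(o: PeriodicOrbit) -> float:
    """max |µ|−1 over genuinely complex multiplier pairs (nan if none)."""
    mu = o.nontrivial_multipliers
    cplx = mu[np.abs(mu.imag) > 1e-4]
    if cplx.size == 0:
        return float("nan")
    return float(np.max(np.abs(cplx)) - 1.0)


def _detect_orbit_bifurcations(branch: PeriodicOrbitBranch, loc_tol: float,
                               par_range=None):
    pv = branch.par_values
    orbits = branch.orbits
    if pv.size < 3:
        return
    dp = np.diff(pv)
    # SNPO: folds in the parameter along the branch, confirmed by a
    # nontrivial multiplier at +1 (distinguishes genuine folds from
    # numerically slow near-Hopf stretches)
    for i in range(1, dp.size):
        if dp[i - 1] * dp[i] < 0:
            # confirm with a multiplier near +1 on one of the neighbouring
            # orbits: on stiff sub-branches the multiplier leaves +1
            # explosively within a single step past the fold
            near_one = min(
                np.min(np.abs(orbits[k].nontrivial_multipliers - 1.0))
                if orbits[k].nontrivial_multipliers.size else np.inf
                for k in (max(i - 1, 0), i, min(i + 1, len(orbits) - 1)))
            if near_one > 0.2:
                continue
            # exclude numerically slow stretches right next to a Hopf
            # point, where the amplitude is tiny and a multiplier is also
            # close to +1
            if np.ptp(orbits[i].nodes[:, 0]) < 2e-2:
                continue
            x = pv[i - 1:i + 2]
            ii = np.array([-1.0, 0.0, 1.0])
            coef = np.polyfit(ii, x, 2)
            s_v = float(np.clip(-coef[1] / (2 * coef[0]), -1, 1)) if coef[0] != 0 else 0.0
            p_fold = float(np.polyval(coef, s_v))
            branch.points.append(OrbitPoint("SNPO", p_fold,
                                            orbits[i].period, i))
    # PD / TR: multiplier tests crossing zero
    for test, kind in ((_pd_test, "PD"), (_tr_test, "TR")):
        g = np.array([test(o) for o in orbits])
        for i in range(1, g.size):
            if np.isfinite(g[i - 1]) and np.isfinite(g[i]) and g[i - 1] * g[i] < 0:
                # secant localization in the parameter (linear in g)
                p_loc = pv[i - 1] + (pv[i] - pv[i - 1]) * (
                    -g[i - 1] / (g[i] - g[i - 1]))
                p_loc = _refine_multiplier_crossing(
                    branch, i - 1, i, test, p_loc, loc_tol)
                mu = orbits[i].nontrivial_multipliers
                branch.points.append(OrbitPoint(kind, float(p_loc),
                                                orbits[i].period, i,
                                                mu[int(np.argmax(np.abs(mu)))]))
    # a branch that terminates inside the parameter range on a
    # finite-amplitude orbit with a multiplier at +1 has crept up to a fold
    # it could not round; record the endpoint as the SNPO
    for i_end in (0, pv.size - 1):
        if par_range is not None and min(abs(pv[i_end] - par_range[0]),
                                         abs(pv[i_end] - par_range[1])) < 1e-6:
            continue    # truncated at the requested box, not a fold
        o = orbits[i_end]
        mu = o.nontrivial_multipliers
        if (mu.size and np.min(np.abs(mu - 1.0)) < 0.05
                and np.ptp(o.nodes[:, 0]) > 2e-2):
            branch.points.append(OrbitPoint("SNPO", float(pv[i_end]),
                                            o.period, i_end))
    branch.points.sort(key=lambda q: q.index)
    # de-duplicate mirror detections (the branch may retrace itself after
    # passing through a Hopf point)
    unique: list[OrbitPoint] = []
    for q in branch.points:
        if any(q.kind == u.kind and abs(q.par_value - u.par_value) < 30 * loc_tol
               for u in unique):
            continue
        unique.append(q)
    branch.points = unique


def _refine_multiplier_crossing(branch, i_a, i_b, test, p_guess, loc_tol):
    """Secant refinement of a multiplier crossing with fixed-parameter solves."""
    o_a, o_b = branch.orbits[i_a], branch.orbits[i_b]
    p_a, p_b = branch.par_values[i_a], branch.par_values[i_b]
    g_a, g_b = test(o_a), test(o_b)
    if abs(p_b - p_a) <= loc_tol:
        return p_guess
    o_near = o_a
    for _ in range(12):
        if abs(p_b - p_a) <= loc_tol or g_b == g_a:
            break
        p_mid = p_a + (p_b - p_a) * (-g_a / (g_b - g_a))
        p_mid = min(max(p_mid, min(p_a, p_b) + 0.05 * abs(p_b - p_a)),
                    max(p_a, p_b) - 0.05 * abs(p_b - p_a))
        p = branch.params.replace(**{branch.par_name: float(p_mid)})
        try:
            o_mid = solve_orbit(branch.model, p, o_near.nodes, o_near.period,
                                taus=o_near.taus)
        except (OrbitError, np.linalg.LinAlgError):
            break
        g_mid = test(o_mid)
        if not np.isfinite(g_mid):
            break
        if g_a * g_mid <= 0:
            p_b, g_b, = p_mid, g_mid
        else:
            p_a, g_a, o_near = p_mid, g_mid, o_mid
    return 0.5 * (p_a + p_b)
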