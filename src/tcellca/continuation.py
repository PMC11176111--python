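"""Equilibrium continuation, bifurcation detection and codim-2 Hopf curves.

Branches of equilibria are traced by pseudo-arclength continuation in one
parameter; Hopf points (a complex eigenvalue pair crossing the imaginary
axis) and saddle-nodes (a real eigenvalue crossing zero) are detected from
eigenvalue counts along the branch and localized by bisection on the
corresponding test function. Curves of Hopf points in two parameters are
continued with the standard extended defining system (equilibrium
condition plus a pure-imaginary eigenpair with two normalization
conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import model as _m
from ._jacobian import jacobian
from .parameters import Parameters
from .systems import resolve

__all__ = ["BranchPoint", "EquilibriumBranch", "Codim2Curve",
           "continue_equilibria", "continue_hopf_2par"]


@dataclass
class BranchPoint:
    """A localized bifurcation point on an equilibrium branch."""

    kind: str                 # "HB" or "SN"
    par_name: str
    par_value: float
    state: np.ndarray
    eigenvalues: np.ndarray
    index: int                # insertion position in the branch arrays
    omega: float = float("nan")          # imaginary part at a Hopf point
    eigenvector: Optional[np.ndarray] = None  # complex eigenvector at a Hopf


@dataclass
class EquilibriumBranch:
    """An equilibrium branch traced in one parameter."""

    model: str
    params: Parameters
    par_name: str
    par_values: np.ndarray
    states: np.ndarray            # (N, n)
    eigenvalues: np.ndarray       # (N, n) complex
    stable: np.ndarray            # (N,) bool
    points: list[BranchPoint] = field(default_factory=list)
    truncated: bool = False

    def hopf_points(self) -> list[BranchPoint]:
        return [p for p in self.points if p.kind == "HB"]

    def saddle_nodes(self) -> list[BranchPoint]:
        return [p for p in self.points if p.kind == "SN"]

    def to_dataframe(self) -> pd.DataFrame:
        n = self.states.shape[1]
        cols = _m.OPEN_VARS if self.model == "open" else _m.CLOSED_VARS
        df = pd.DataFrame(self.states, columns=list(cols[:n]))
        df.insert(0, self.par_name, self.par_values)
        df["re_lambda_max"] = np.max(self.eigenvalues.real, axis=1)
        df["stable"] = self.stable
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _eig_sorted(J: np.ndarray) -> np.ndarray:
    e = np.linalg.eigvals(J)
    return e[np.argsort(-e.real)]


def _hopf_test(eig: np.ndarray) -> float:
    """Real part of the rightmost complex eigenvalue pair (nan if none)."""
    cplx = eig[np.abs(eig.imag) > 1e-9]
    if cplx.size == 0:
        return float("nan")
    return float(np.max(cplx.real))


def _solve_equilibrium_at(model: str, params: Parameters, par_name: str,
                          par_value: float, guess: np.ndarray,
                          tol: float = 1e-11) -> np.ndarray:
    from .simulate import find_equilibrium
    p = params.replace(**{par_name: par_value})
    return find_equilibrium(model, p, guess, tol=tol).state


def continue_equilibria(model: str, params: Parameters, par_name: str,
                        par_range: tuple[float, float], start,
                        ds0: float = 1e-3, ds_max: float = 2e-2,
                        ds_min: float = 1e-9, max_steps: int = 2000,
                        loc_tol: float = 1e-5) -> EquilibriumBranch:
    """Trace the equilibrium branch from ``start`` across ``par_range``.

    ``start`` must be (close to) an equilibrium at ``par_range[0]``. The
    branch is continued by pseudo-arclength with adaptive step until the
    parameter leaves ``par_range`` or ``max_steps`` is reached; Hopf and
    saddle-node points are localized to ``loc_tol`` in the parameter.
    """
    from .simulate import find_equilibrium

    lo, hi = float(min(par_range)), float(max(par_range))
    p_cur = float(par_range[0])
    direction = 1.0 if par_range[1] >= par_range[0] else -1.0

    ops = resolve(model)
    n = ops.n

    def F(y, pv):
        return ops.rhs(y, params.replace(**{par_name: pv}))

    def Jx(y, pv):
        return ops.jac(y, params.replace(**{par_name: pv}))

    def Jp(y, pv):
        return ops.dpar(y, params.replace(**{par_name: pv}), par_name)

    y = find_equilibrium(model, params.replace(**{par_name: p_cur}), start).state

    p_scale = max(hi - lo, 1e-6)

    def weights(y):
        # component scales for the arclength metric: states by magnitude,
        # the parameter by its range
        return np.r_[np.maximum(np.abs(y), 1e-2), p_scale]

    def tangent(y, pv, prev=None):
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = Jx(y, pv)
        A[:n, n] = Jp(y, pv)
        A[n, :] = prev if prev is not None else np.r_[np.zeros(n), 1.0]
        b = np.zeros(n + 1)
        b[n] = 1.0
        try:
            t = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            t = np.linalg.lstsq(A, b, rcond=None)[0]
        return t / np.linalg.norm(t / weights(y))

    pars = [p_cur]
    states = [y.copy()]
    eigs = [_eig_sorted(Jx(y, p_cur))]
    points: list[BranchPoint] = []
    truncated = False

    t = tangent(y, p_cur)
    if t[n] * direction < 0:
        t = -t
    ds = ds0

    def newton_plc(y0, p0, tvec, ds):
        """One pseudo-arclength corrector step (scaled arclength metric)."""
        w = weights(y0)
        u_pred = np.r_[y0, p0] + ds * tvec
        u = u_pred.copy()
        for _ in range(12):
            yv, pv = u[:n], u[n]
            r = np.r_[F(yv, pv), (tvec / w**2) @ (u - u_pred)]
            if np.max(np.abs(r)) < 1e-11:
                return yv, pv, True
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = Jx(yv, pv)
            A[:n, n] = Jp(yv, pv)
            A[n, :] = tvec / w**2
            try:
                du = np.linalg.solve(A, -r)
            except np.linalg.LinAlgError:
                return None, None, False
            u = u + du
            if not np.all(np.isfinite(u)):
                return None, None, False
        return None, None, False

    fails = 0
    for _ in range(max_steps):
        y_new, p_new, ok = newton_plc(y, p_cur, t, ds)
        if not ok:
            ds *= 0.5
            fails += 1
            if ds < ds_min or fails > 40:
                truncated = True
                break
            continue
        fails = 0
        t_new = tangent(y_new, p_new, prev=t)
        if t_new @ t < 0:
            t_new = -t_new
        eig_new = _eig_sorted(Jx(y_new, p_new))

        # -- detection between (y, p_cur) and (y_new, p_new)
        _detect(model, params, par_name, pars[-1], states[-1], eigs[-1],
                p_new, y_new, eig_new, points, len(pars), loc_tol)

        pars.append(p_new)
        states.append(y_new.copy())
        eigs.append(eig_new)
        y, p_cur, t = y_new, p_new, t_new
        ds = min(ds * 1.3, ds_max)
        if p_cur < lo - 1e-12 or p_cur > hi + 1e-12:
            break

    eig_arr = np.array(eigs)
    return EquilibriumBranch(
        model=model, params=params, par_name=par_name,
        par_values=np.array(pars), states=np.array(states),
        eigenvalues=eig_arr,
        stable=np.all(eig_arr.real < 0, axis=1),
        points=points, truncated=truncated,
    )


def _detect(model, params, par_name, p_a, y_a, eig_a, p_b, y_b, eig_b,
            points, index, loc_tol):
    """Detect and localize HB/SN between two accepted branch points."""
    n_unst_a = int(np.sum(eig_a.real > 0))
    n_unst_b = int(np.sum(eig_b.real > 0))
    if n_unst_a == n_unst_b:
        return
    g_a, g_b = _hopf_test(eig_a), _hopf_test(eig_b)
    is_hopf = (abs(n_unst_a - n_unst_b) == 2 and np.isfinite(g_a)
               and np.isfinite(g_b) and g_a * g_b < 0)
    det_a = float(np.real(np.prod(eig_a)))
    det_b = float(np.real(np.prod(eig_b)))
    is_sn = det_a * det_b < 0
    if not is_hopf and not is_sn:
        return
    kind = "HB" if is_hopf else "SN"

    ops = resolve(model)

    def test(pv, guess):
        y = _solve_equilibrium_at(model, params, par_name, pv, guess)
        eig = _eig_sorted(ops.jac(y, params.replace(**{par_name: pv})))
        g = _hopf_test(eig) if kind == "HB" else float(np.real(np.prod(eig)))
        return g, y, eig

    pa, pb = p_a, p_b
    ga, _, _ = test(pa, y_a)
    gb, _, _ = test(pb, y_b)
    if not (np.isfinite(ga) and np.isfinite(gb)) or ga * gb > 0:
        return
    y_guess = 0.5 * (y_a + y_b)
    y_loc, eig_loc, p_loc = y_guess, None, 0.5 * (pa + pb)
    g_loc = np.inf
    # bisect to the requested parameter accuracy, then keep halving until
    # the test function itself is driven below 1e-7 (a detected Hopf must
    # carry a pair with |Re| < 1e-6)
    for _ in range(80):
        if abs(pb - pa) <= loc_tol and abs(g_loc) < 1e-7:
            break
        if abs(pb - pa) < 1e-13:
            break
        pm = 0.5 * (pa + pb)
        gm, ym, eigm = test(pm, y_guess)
        y_guess, y_loc, eig_loc, p_loc, g_loc = ym, ym, eigm, pm, gm
        if ga * gm <= 0:
            pb, gb = pm, gm
        else:
            pa, ga = pm, gm
    if eig_loc is None:
        _, y_loc, eig_loc = test(p_loc, y_guess)
    point = BranchPoint(kind=kind, par_name=par_name, par_value=float(p_loc),
                        state=y_loc, eigenvalues=eig_loc, index=index)
    if kind == "HB":
        cplx = eig_loc[eig_loc.imag > 1e-9]
        lam = cplx[np.argmin(np.abs(cplx.real))]
        point.omega = float(lam.imag)
        J = ops.jac(y_loc, params.replace(**{par_name: float(p_loc)}))
        w, V = np.linalg.eig(J)
        k = int(np.argmin(np.abs(w - lam)))
        point.eigenvector = V[:, k]
    points.append(point)


@dataclass
class Codim2Curve:
    """A curve of Hopf points in a two-parameter plane."""

    model: str
    params: Parameters
    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    p2_values: np.ndarray
    states: np.ndarray
    omegas: np.ndarray
    kind: str = "HB"
    closed: bool = False
    truncated: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({self.p1_name: self.p1_values,
                           self.p2_name: self.p2_values,
                           "omega": self.omegas})
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def continue_hopf_2par(model: str, params: Parameters, p1_name: str,
                       p2_name: str, hb_start: BranchPoint,
                       box: dict[str, tuple[float, float]] | None = None,
                       ds0: float = 5e-3, ds_max: float = 5e-2,
                       max_steps: int = 3000) -> Codim2Curve:
    """Continue a Hopf point in the (p1, p2) plane.

    The extended defining system couples the equilibrium condition
    f(x; p1, p2) = 0 with a pure-imaginary eigenpair J v = iω v and two
    normalization conditions pinning the eigenvector's scale and phase.
    The curve is traced in both directions until it closes on itself or
    leaves ``box`` (default: p1, p2 within broad positive bounds).
    """
    ops = resolve(model)
    n = ops.n
    box = box or {}
    b1 = box.get(p1_name, (1e-6, 1e6))
    b2 = box.get(p2_name, (1e-6, 1e6))

    if hb_start.par_name not in (p1_name, p2_name):
        raise ValueError("hb_start was localized in neither p1 nor p2")
    p1_0 = hb_start.par_value if hb_start.par_name == p1_name else getattr(params, p1_name)
    p2_0 = hb_start.par_value if hb_start.par_name == p2_name else getattr(params, p2_name)

    v0 = hb_start.eigenvector
    omega0 = abs(hb_start.omega)
    if v0 is None or not np.isfinite(omega0):
        raise ValueError("hb_start carries no eigenpair; localize it first")

    # normalization vector: fix c^T v = 1 (complex), with real c
    c_norm = np.real(v0).copy()
    if np.linalg.norm(c_norm) < 1e-12:
        c_norm = np.imag(v0).copy()
    c_norm /= np.linalg.norm(c_norm)
    v0 = v0 / (c_norm @ v0)
    x0 = hb_start.state.copy()

    # unknown vector u = (x, vr, vi, omega, p1, p2)
    def unpack(u):
        return (u[:n], u[n:2 * n], u[2 * n:3 * n], u[3 * n], u[3 * n + 1],
                u[3 * n + 2])

    class _EvalError(Exception):
        pass

    def residual(u):
        x, vr, vi, om, p1, p2 = unpack(u)
        try:
            p = params.replace(**{p1_name: float(p1), p2_name: float(p2)})
        except ValueError as exc:   # iterate left the admissible parameter set
            raise _EvalError(str(exc)) from exc
        J = ops.jac(x, p)
        return np.r_[ops.rhs(x, p),
                     J @ vr + om * vi,
                     J @ vi - om * vr,
                     c_norm @ vr - 1.0,
                     c_norm @ vi]

    N = 3 * n + 3

    def fd_jac(u):
        r0 = residual(u)
        A = np.zeros((N - 1 + 1, N))  # (3n+2) rows + arclength added later
        A = np.zeros((3 * n + 2, N))
        for j in range(N):
            h = 1e-7 * (1.0 + abs(u[j]))
            up = u.copy()
            up[j] += h
            A[:, j] = (residual(up) - r0) / h
        return A, r0

    u = np.r_[x0, np.real(v0), np.imag(v0), omega0, p1_0, p2_0]

    # polish the starting point with pinned p2
    for _ in range(30):
        A, r = fd_jac(u)
        if np.max(np.abs(r)) < 1e-10:
            break
        Afix = np.vstack([A, np.eye(N)[-1]])
        rfix = np.r_[r, 0.0]
        du = np.linalg.lstsq(Afix, -rfix, rcond=None)[0]
        u = u + du

    scale = np.ones(N)
    scale[-2] = max(b1[1] - b1[0], 1e-3)
    scale[-1] = max(b2[1] - b2[0], 1e-3)

    def tangent(u, prev=None):
        A, _ = fd_jac(u)
        B = np.vstack([A, prev if prev is not None else np.eye(N)[-1]])
        b = np.zeros(3 * n + 3)
        b[-1] = 1.0
        t = np.linalg.lstsq(B, b, rcond=None)[0]
        return t / np.linalg.norm(t / scale)

    def trace(direction: float):
        pts = []
        uu = u.copy()
        t = tangent(uu) * direction
        ds = ds0
        fails = 0
        for step in range(max_steps):
            pred = uu + ds * t
            uc = pred.copy()
            ok = False
            for _ in range(10):
                try:
                    A, r = fd_jac(uc)
                except _EvalError:
                    break
                rr = np.r_[r, (t / scale**2) @ (uc - pred)]
                if np.max(np.abs(rr)) < 1e-9:
                    ok = True
                    break
                B = np.vstack([A, t / scale**2])
                try:
                    du = np.linalg.solve(B, -rr)
                except np.linalg.LinAlgError:
                    break
                uc = uc + du
                if not np.all(np.isfinite(uc)):
                    break
            if not ok:
                ds *= 0.5
                fails += 1
                if ds < 1e-8 or fails > 40:
                    return pts, True, False
                continue
            fails = 0
            t_new = tangent(uc, prev=t)
            if t_new @ t < 0:
                t_new = -t_new
            pts.append(uc.copy())
            p1v, p2v = uc[-2], uc[-1]
            if not (b1[0] <= p1v <= b1[1] and b2[0] <= p2v <= b2[1]):
                return pts, True, False
            if step > 10:
                d0 = np.linalg.norm((uc - u) / scale)
                if d0 < 1.5 * ds:
                    return pts, False, True   # curve closed on itself
            uu, t = uc, t_new
            ds = min(ds * 1.25, ds_max)
        return pts, True, False

    fwd, trunc_f, closed = trace(+1.0)
    if closed:
        all_pts = [u] + fwd
        truncated = False
    else:
        bwd, trunc_b, _ = trace(-1.0)
        all_pts = list(reversed(bwd)) + [u] + fwd
        truncated = trunc_f or trunc_b
    arr = np.array(all_pts)
    return Codim2Curve(
        model=model, params=params, p1_name=p1_name, p2_name=p2_name,
        p1_values=arr[:, -2], p2_values=arr[:, -1],
        states=arr[:, :n], omegas=arr[:, 3 * n],
        closed=closed, truncated=truncated,
    )
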