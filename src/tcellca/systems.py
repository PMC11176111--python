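"""Resolution of dynamical systems for the numerical machinery.

The continuation and periodic-orbit code operates on a small operations
bundle (dimension, rhs, Jacobian, parameter derivative, and an optional
fused variational rhs). The two built-in models resolve to generated fast
kernels; any object exposing ``n_vars`` and ``rhs(y, params)`` — e.g. an
analytically constructed test system — can be passed wherever a model
name is accepted, with missing derivatives supplied by central finite
differences (step 1e-7·(1+|x|)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .parameters import PARAM_ORDER, Parameters

__all__ = ["SystemOps", "CustomSystem", "resolve"]


@dataclass
class SystemOps:
    n: int
    rhs: Callable                 # (y, params) -> (n,)
    jac: Callable                 # (y, params) -> (n, n)
    dpar: Callable                # (y, params, name) -> (n,)
    rhs_var: Optional[Callable]   # (z, pv, ip) fused kernel, or None
    name: str


def _fd_jac(rhs):
    def jac(y, params):
        y = np.asarray(y, dtype=float)
        n = y.size
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * (1.0 + abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            J[:, j] = (np.asarray(rhs(yp, params)) -
                       np.asarray(rhs(ym, params))) / (2 * h)
        return J
    return jac


def _fd_dpar(rhs):
    def dpar(y, params, name):
        v = getattr(params, name)
        h = 1e-7 * (1.0 + abs(v))
        pp = params.replace(**{name: v + h})
        try:
            pm = params.replace(**{name: v - h})
        except ValueError:    # one-sided at the boundary of validity
            return (np.asarray(rhs(y, pp)) - np.asarray(rhs(y, params))) / h
        return (np.asarray(rhs(y, pp)) - np.asarray(rhs(y, pm))) / (2 * h)
    return dpar


@dataclass
class CustomSystem:
    """A user-supplied vector field parameterized by :class:`Parameters`.

    Only ``rhs`` is required; the Jacobian and parameter derivatives
    default to finite differences.
    """

    n_vars: int
    rhs: Callable                          # (y, params) -> (n,)
    jac: Optional[Callable] = None         # (y, params) -> (n, n)
    dpar: Optional[Callable] = None        # (y, params, name) -> (n,)
    name: str = "custom"


def resolve(model) -> SystemOps:
    """Map a model name or :class:`CustomSystem` to its operations."""
    if isinstance(model, str):
        from . import _kernels as K
        if model == "open":
            return SystemOps(
                5,
                rhs=lambda y, p: K.rhs_open(np.asarray(y, float), p.vector),
                jac=lambda y, p: K.jac_open(np.asarray(y, float), p.vector),
                dpar=lambda y, p, nm: K.dpar_open(
                    np.asarray(y, float), p.vector)[:, PARAM_ORDER.index(nm)],
                rhs_var=K.rhs_var_open, name="open")
        if model == "closed":
            return SystemOps(
                3,
                rhs=lambda y, p: K.rhs_closed(np.asarray(y, float), p.vector),
                jac=lambda y, p: K.jac_closed(np.asarray(y, float), p.vector),
                dpar=lambda y, p, nm: K.dpar_closed(
                    np.asarray(y, float), p.vector)[:, PARAM_ORDER.index(nm)],
                rhs_var=K.rhs_var_closed, name="closed")
        raise ValueError(f"unknown model {model!r}")
    if isinstance(model, CustomSystem):
        jac = model.jac or _fd_jac(model.rhs)
        dpar = model.dpar or _fd_dpar(model.rhs)
        return SystemOps(model.n_vars, rhs=model.rhs, jac=jac, dpar=dpar,
                         rhs_var=None, name=model.name)
    if isinstance(model, SystemOps):
        return model
    raise TypeError(f"cannot resolve a system from {type(model)!r}")


def make_rhs_var(ops: SystemOps):
    """Fused state+variational(+sensitivity) rhs for a generic system."""
    def rhs_var(z, params, par_name):
        n = ops.n
        x = z[:n]
        J = ops.jac(x, params)
        out = np.empty(z.size)
        out[:n] = ops.rhs(x, params)
        Phi = z[n:n + n * n].reshape(n, n)
        out[n:n + n * n] = (J @ Phi).ravel()
        if z.size > n + n * n:
            out[n + n * n:] = J @ z[n + n * n:] + ops.dpar(x, params, par_name)
        return out
    return rhs_var
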