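"""Analytic Jacobians of the vector fields, generated with sympy.

The state Jacobian and per-parameter derivative vectors are built
symbolically once per process and lambdified to plain numpy functions.
They are used by the Newton solvers, the variational (monodromy)
integration and the continuation tangents; a finite-difference
cross-check lives in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .parameters import PARAM_ORDER as _PARAM_NAMES
from .parameters import Parameters


@lru_cache(maxsize=1)
def _symbolic():
    c, ce, h, p, s = sp.symbols("c c_e h p s", real=True)
    par = {name: sp.Symbol(name, positive=(name not in ("V_PLC", "delta")))
           for name in _PARAM_NAMES}

    c4 = c**4
    phi_c = c4 / (c4 + par["K_c"] ** 4)
    phi_p = p**2 / (p**2 + par["K_p"] ** 2)
    phi_p_down = par["K_p"] ** 2 / (p**2 + par["K_p"] ** 2)
    h_inf = par["K_h"] ** 4 / (par["K_h"] ** 4 + c4)
    tau_h = par["tau_max"] * par["K_tau"] ** 4 / (par["K_tau"] ** 4 + c4)
    beta = phi_p * phi_c * h
    alpha = phi_p_down * (1 - phi_c * h_inf)
    P0 = beta / (beta + par["k_beta"] * (beta + alpha))

    def serca(cv, cev):
        return par["V_SERCA"] * (cv**2 - par["K_bar"] * cev**2) / (cv**2 + par["K_SERCA"] ** 2)

    J_pm = par["V_PM"] * c**2 / (c**2 + par["K_PM"] ** 2)
    J_soce = par["V_SOCE"] / (1 + sp.exp(par["s1"] * (ce - par["K_e"])))
    J_degr = par["V_deg"] * c**2 / (c**2 + par["K_deg"] ** 2) * p

    J_ipr_open = par["k_f"] * P0 * (ce - c)
    f_open = sp.Matrix([
        J_ipr_open - serca(c, ce) + par["delta"] * (s - J_pm),
        par["gamma"] * (serca(c, ce) - J_ipr_open),
        (h_inf - h) / tau_h,
        (par["V_PLC"] - J_degr) / par["tau_p"],
        (J_soce - s) / par["tau_s"],
    ])

    ce_cl = par["gamma"] * (par["C_t"] - c)
    J_ipr_cl = par["k_f"] * P0 * (ce_cl - c)
    f_closed = sp.Matrix([
        J_ipr_cl - serca(c, ce_cl),
        (h_inf - h) / tau_h,
        (par["V_PLC"] - J_degr) / par["tau_p"],
    ])

    return (c, ce, h, p, s), par, f_open, f_closed


@lru_cache(maxsize=4)
def _jac_fn(model: str):
    (c, ce, h, p, s), par, f_open, f_closed = _symbolic()
    pargs = [par[name] for name in _PARAM_NAMES]
    if model == "open":
        J = f_open.jacobian([c, ce, h, p, s])
        return sp.lambdify((c, ce, h, p, s, *pargs), J, modules="numpy")
    J = f_closed.jacobian([c, h, p])
    return sp.lambdify((c, h, p, *pargs), J, modules="numpy")


@lru_cache(maxsize=64)
def _dpar_fn(model: str, par_name: str):
    (c, ce, h, p, s), par, f_open, f_closed = _symbolic()
    pargs = [par[name] for name in _PARAM_NAMES]
    if model == "open":
        expr = f_open.diff(par[par_name])
        return sp.lambdify((c, ce, h, p, s, *pargs), expr, modules="numpy")
    expr = f_closed.diff(par[par_name])
    return sp.lambdify((c, h, p, *pargs), expr, modules="numpy")


def _pvals(params: Parameters) -> tuple[float, ...]:
    return tuple(getattr(params, name) for name in _PARAM_NAMES)


def sympy_jacobian(model: str, y, params: Parameters) -> np.ndarray:
    """Jacobian evaluated through the symbolic route (reference/testing)."""
    y = np.asarray(y, dtype=float)
    return np.asarray(_jac_fn(model)(*y, *_pvals(params)), dtype=float)


def open_jacobian(y, params: Parameters) -> np.ndarray:
    from ._kernels import jac_open
    return jac_open(np.asarray(y, dtype=float), params.vector)


def closed_jacobian(y, params: Parameters) -> np.ndarray:
    from ._kernels import jac_closed
    return jac_closed(np.asarray(y, dtype=float), params.vector)


def parameter_derivative(model: str, y, params: Parameters, par_name: str) -> np.ndarray:
    """∂f/∂par at state y, as a length-n vector."""
    from ._kernels import dpar_closed, dpar_open
    ip = _PARAM_NAMES.index(par_name)
    fn = dpar_open if model == "open" else dpar_closed
    return fn(np.asarray(y, dtype=float), params.vector)[:, ip]


def rhs_value(model: str, y, params: Parameters) -> np.ndarray:
    """Fast kernel evaluation of the right-hand side (no validation)."""
    from ._kernels import rhs_closed, rhs_open
    fn = rhs_open if model == "open" else rhs_closed
    return fn(np.asarray(y, dtype=float), params.vector)


def jacobian(model: str, y, params: Parameters) -> np.ndarray:
    return open_jacobian(y, params) if model == "open" else closed_jacobian(y, params)
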