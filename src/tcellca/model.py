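"""Fluxes and right-hand sides of the open- and closed-cell Ca²⁺ models.

The open cell is a five-variable system (c, c_e, h, p, s):

    dc/dt   = J_IP3R − J_SERCA + δ(s − J_PM)
    dc_e/dt = γ(J_SERCA − J_IP3R)
    τ_h dh/dt = h_∞ − h
    τ_p dp/dt = V_PLC − J_deg
    τ_s ds/dt = J_SOCE − s

With δ = 0 the total free Ca²⁺, C_t = c + c_e/γ, is conserved and s
decouples; eliminating c_e = γ(C_t − c) gives the closed-cell system in
(c, h, p). The closed-cell right-hand side is implemented independently
(its fluxes written in terms of c and C_t) and cross-validated against the
open-cell form under substitution.

Flux expressions
----------------
IP₃R (gating by IP₃, Ca²⁺ activation and slow Ca²⁺ inactivation):

    φ_c = c⁴/(c⁴+K_c⁴), φ_p = p²/(p²+K_p²), φ̄_p = K_p²/(p²+K_p²)
    h_∞ = K_h⁴/(K_h⁴+c⁴), τ_h(c) = τ_max K_τ⁴/(K_τ⁴+c⁴)
    β = φ_p φ_c h, α = φ̄_p (1 − φ_c h_∞)
    P₀ = β/(β + k_β(β+α)), J_IP3R = k_f P₀ (c_e − c)

Bidirectional SERCA, Hill-2 PMCA, sigmoidal store-operated influx and
Ca²⁺-stimulated IP₃ degradation:

    J_SERCA = V_SERCA (c² − K̄ c_e²)/(c² + K_SERCA²)
    J_PM    = V_PM c²/(c² + K_PM²)
    J_SOCE  = V_SOCE / (1 + exp(s₁(c_e − K_e)))
    J_deg   = V_deg c²/(c² + K_deg²) · p
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .parameters import Parameters

__all__ = [
    "OpenState", "ClosedState", "FluxBreakdown",
    "j_soce", "j_deg", "j_serca", "j_pm", "ip3r_gating", "j_ip3r",
    "er_fluxes", "rhs_open", "rhs_closed", "jac_open", "jac_closed",
    "OPEN_VARS", "CLOSED_VARS",
]

OPEN_VARS = ("c", "c_e", "h", "p", "s")
CLOSED_VARS = ("c", "h", "p")


@dataclass(frozen=True)
class OpenState:
    """Phase-space point of the open-cell model.

    c, c_e in µM; h dimensionless in [0,1]; p in µM; s in µM/s.
    """

    c: float
    c_e: float
    h: float
    p: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.c_e, self.h, self.p, self.s], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "OpenState":
        return cls(*(float(v) for v in y))

    def validate(self, params: Parameters | None = None) -> "OpenState":
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite state")
        if self.c < 0 or self.c_e < 0 or self.p < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if params is not None and not 0.0 <= self.s <= params.V_SOCE:
            raise ValueError("s outside the attracting range [0, V_SOCE]")
        return self


@dataclass(frozen=True)
class ClosedState:
    """Phase-space point of the closed-cell model (c, h, p).

    The ER concentration is implied: c_e = γ(C_t − c), which requires
    c ≤ C_t.
    """

    c: float
    h: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.h, self.p], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ClosedState":
        return cls(*(float(v) for v in y))

    def c_e(self, params: Parameters) -> float:
        return params.gamma * (params.C_t - self.c)

    def validate(self, params: Parameters | None = None) -> "ClosedState":
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite state")
        if self.c < 0 or self.p < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if params is not None and self.c > params.C_t:
            raise ValueError("c exceeds the total free Ca2+ C_t")
        return self


@dataclass(frozen=True)
class FluxBreakdown:
    """All fluxes (µM/s) and gating quantities at one state."""

    J_IP3R: float
    J_SERCA: float
    J_PM: float
    J_SOCE: float
    J_deg: float
    P0: float
    h_inf: float
    tau_h: float

    def as_dict(self) -> dict[str, float]:
        return {
            "J_IP3R": self.J_IP3R, "J_SERCA": self.J_SERCA, "J_PM": self.J_PM,
            "J_SOCE": self.J_SOCE, "J_deg": self.J_deg, "P0": self.P0,
            "h_inf": self.h_inf, "tau_h": self.tau_h,
        }


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input")


def j_soce(c_e, params: Parameters):
    """Store-operated (CRAC) influx rate as a function of ER Ca²⁺.

    A decreasing sigmoid in c_e with midpoint K_e, steepness s1 and maximum
    V_SOCE: the emptier the store, the stronger the influx.
    """
    _check_finite(c_e)
    if np.any(np.asarray(c_e) < 0):
        raise ValueError("c_e must be non-negative")
    x = np.multiply(params.s1, np.subtract(c_e, params.K_e))
    # logistic written via exp with clipping to avoid overflow at large c_e
    return params.V_SOCE / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


def j_deg(c, p, params: Parameters):
    """Ca²⁺-stimulated IP₃ degradation rate, linear in p."""
    _check_finite(c, p)
    if np.any(np.asarray(c) < 0) or np.any(np.asarray(p) < 0):
        raise ValueError("c and p must be non-negative")
    c2 = np.square(c)
    return params.V_deg * c2 / (c2 + params.K_deg**2) * p


def j_serca(c, c_e, params: Parameters):
    """Bidirectional SERCA pump flux (positive = into the ER)."""
    c2 = np.square(c)
    return params.V_SERCA * (c2 - params.K_bar * np.square(c_e)) / (c2 + params.K_SERCA**2)


def j_pm(c, params: Parameters):
    """Unidirectional Hill-2 PMCA extrusion flux."""
    c2 = np.square(c)
    return params.V_PM * c2 / (c2 + params.K_PM**2)


def ip3r_gating(c, p, h, params: Parameters):
    """IP₃R open probability P₀, gate target h_∞ and gate timescale τ_h(c)."""
    c4 = np.square(np.square(c))
    p2 = np.square(p)
    phi_c = c4 / (c4 + params.K_c**4)
    phi_p = p2 / (p2 + params.K_p**2)
    phi_p_down = params.K_p**2 / (p2 + params.K_p**2)
    h_inf = params.K_h**4 / (params.K_h**4 + c4)
    tau_h = params.tau_max * params.K_tau**4 / (params.K_tau**4 + c4)
    beta = phi_p * phi_c * h
    alpha = phi_p_down * (1.0 - phi_c * h_inf)
    P0 = beta / (beta + params.k_beta * (beta + alpha))
    return P0, h_inf, tau_h


def j_ip3r(c, c_e, h, p, params: Parameters):
    """IP₃R release flux k_f·P₀·(c_e − c)."""
    P0, _, _ = ip3r_gating(c, p, h, params)
    return params.k_f * P0 * (c_e - c)


def er_fluxes(state: OpenState | ClosedState | Iterable[float],
              params: Parameters, *, model: str | None = None) -> FluxBreakdown:
    """Evaluate every flux and gating quantity at one state.

    ``state`` may be an :class:`OpenState`, a :class:`ClosedState` (then
    c_e = γ(C_t − c)), or a raw array whose length (5 or 3) picks the model
    unless ``model`` is given explicitly.
    """
    if isinstance(state, OpenState):
        c, c_e, h, p = state.c, state.c_e, state.h, state.p
    elif isinstance(state, ClosedState):
        c, h, p = state.c, state.h, state.p
        c_e = params.gamma * (params.C_t - c)
    else:
        y = np.asarray(state, dtype=float)
        kind = model or ("open" if y.size == 5 else "closed")
        if kind == "open":
            c, c_e, h, p = y[0], y[1], y[2], y[3]
        else:
            c, h, p = y[0], y[1], y[2]
            c_e = params.gamma * (params.C_t - c)
    _check_finite(c, c_e, h, p)
    P0, h_inf, tau_h = ip3r_gating(c, p, h, params)
    return FluxBreakdown(
        J_IP3R=float(params.k_f * P0 * (c_e - c)),
        J_SERCA=float(j_serca(c, c_e, params)),
        J_PM=float(j_pm(c, params)),
        J_SOCE=float(j_soce(c_e, params)),
        J_deg=float(j_deg(c, p, params)),
        P0=float(P0), h_inf=float(h_inf), tau_h=float(tau_h),
    )


def rhs_open(t: float, y: np.ndarray, params: Parameters) -> np.ndarray:
    """Right-hand side of the open-cell model; y = (c, c_e, h, p, s)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs_open")
    c, c_e, h, p, s = y
    P0, h_inf, tau_h = ip3r_gating(c, p, h, params)
    J_ipr = params.k_f * P0 * (c_e - c)
    J_ser = j_serca(c, c_e, params)
    return np.array([
        J_ipr - J_ser + params.delta * (s - j_pm(c, params)),
        params.gamma * (J_ser - J_ipr),
        (h_inf - h) / tau_h,
        (params.V_PLC - j_deg(c, p, params)) / params.tau_p,
        (j_soce(c_e, params) - s) / params.tau_s,
    ])


def rhs_closed(t: float, y: np.ndarray, params: Parameters) -> np.ndarray:
    """Right-hand side of the closed-cell model; y = (c, h, p).

    The ER variable is eliminated through c_e = γ(C_t − c); the fluxes are
    written directly in terms of c and C_t.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs_closed")
    c, h, p = y
    if c > params.C_t:
        raise ValueError("c exceeds the total free Ca2+ C_t")
    c_e = params.gamma * (params.C_t - c)
    P0, h_inf, tau_h = ip3r_gating(c, p, h, params)
    J_ipr = params.k_f * P0 * (c_e - c)
    c2 = c * c
    J_ser = params.V_SERCA * (c2 - params.K_bar * params.gamma**2
                              * (params.C_t - c) ** 2) / (c2 + params.K_SERCA**2)
    return np.array([
        J_ipr - J_ser,
        (h_inf - h) / tau_h,
        (params.V_PLC - j_deg(c, p, params)) / params.tau_p,
    ])


def rhs(model: str):
    """Return the right-hand-side function for ``model`` ('open'|'closed')."""
    if model == "open":
        return rhs_open
    if model == "closed":
        return rhs_closed
    raise ValueError(f"unknown model {model!r}")


def n_vars(model: str) -> int:
    return 5 if model == "open" else 3


def jac_open(t: float, y: np.ndarray, params: Parameters) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_open` (generated symbolically)."""
    from ._jacobian import open_jacobian
    return open_jacobian(y, params)


def jac_closed(t: float, y: np.ndarray, params: Parameters) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_closed` (generated symbolically)."""
    from ._jacobian import closed_jacobian
    return closed_jacobian(y, params)


def jac(model: str):
    return jac_open if model == "open" else jac_closed
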