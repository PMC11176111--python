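"""Model parameters and their serialization.

All concentrations are in µM, all times in seconds, all rates in µM/s.
The default constructor reproduces the published reference parameter set of
the T-lymphocyte Ca²⁺ model; the stimulation strength ``V_PLC`` and the
plasma-membrane transport ratio ``delta`` are scenario-dependent and must be
supplied explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

__all__ = ["Parameters", "load_parameters", "default_parameter_file",
           "PARAM_ORDER"]

# canonical field ordering of the numeric parameter vector used by the
# generated kernels
PARAM_ORDER = (
    "V_PLC", "delta", "gamma", "V_PM", "K_PM", "V_SOCE", "s1", "K_e",
    "tau_s", "V_SERCA", "K_SERCA", "K_bar", "k_f", "k_beta", "K_p", "K_c",
    "K_h", "tau_max", "K_tau", "tau_p", "V_deg", "K_deg", "C_t",
)


@dataclass(frozen=True)
class Parameters:
    """Parameter set of the open- and closed-cell Ca²⁺ models.

    Attributes
    ----------
    V_PLC:
        Maximal rate of IP₃ production by PLC, µM/s. The principal
        bifurcation parameter (stimulation strength).
    delta:
        Dimensionless ratio of plasma-membrane to ER flux rates. ``delta=0``
        closes the cell to extracellular Ca²⁺ exchange.
    gamma:
        Cytoplasm:ER volume ratio (dimensionless).
    V_PM, K_PM:
        Maximal rate (µM/s) and half-activation concentration (µM) of the
        Hill-2 PMCA pump.
    V_SOCE, s1, K_e, tau_s:
        Maximal store-operated influx rate (µM/s), steepness of the CRAC
        activation sigmoid (1/µM), its midpoint in ER Ca²⁺ (µM), and the
        CRAC-channel formation timescale (s).
    V_SERCA, K_SERCA, K_bar:
        Maximal rate (µM/s), half-activation concentration (µM) and
        dimensionless reverse-mode constant of the bidirectional SERCA pump.
    k_f, k_beta, K_p, K_c, K_h:
        IP₃R gating constants: maximal receptor flux scale (µM... per s per
        µM of gradient, written k_f in the field), mode-weighting constant
        (dimensionless), IP₃ half-activation (µM), Ca²⁺ half-activation of
        receptor opening (µM), Ca²⁺ half-inactivation (µM).
    tau_max, K_tau:
        Maximal IP₃R inactivation-gate timescale (s) and the Ca²⁺ midpoint
        (µM) of its modulation by cytosolic Ca²⁺.
    tau_p, V_deg, K_deg:
        IP₃ turnover timescale (s), maximal Ca²⁺-dependent degradation rate
        (per unit IP₃, µM/s) and its Ca²⁺ half-activation (µM).
    C_t:
        Total free Ca²⁺ (µM), conserved in the closed cell; only meaningful
        when ``delta=0`` / the closed-cell model is used.
    """

    V_PLC: float
    delta: float
    gamma: float = 5.5
    V_PM: float = 3.0
    K_PM: float = 0.2
    V_SOCE: float = 3.0
    s1: float = 0.2
    K_e: float = 800.0
    tau_s: float = 15.0
    V_SERCA: float = 2.0
    K_SERCA: float = 0.19
    K_bar: float = 1e-8
    k_f: float = 1.6
    k_beta: float = 0.4
    K_p: float = 10.0
    K_c: float = 0.16
    K_h: float = 0.168
    tau_max: float = 7.5
    K_tau: float = 0.095
    tau_p: float = 2.0
    V_deg: float = 6.0
    K_deg: float = 0.5
    C_t: float = 140.0

    _POSITIVE = (
        "gamma", "V_PM", "K_PM", "V_SOCE", "s1", "K_e", "tau_s", "V_SERCA",
        "K_SERCA", "k_f", "k_beta", "K_p", "K_c", "K_h", "tau_max", "K_tau",
        "tau_p", "V_deg", "K_deg", "C_t",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.V_PLC < 0:
            raise ValueError("V_PLC must be non-negative")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.K_bar < 0:
            raise ValueError("K_bar must be non-negative")
        import numpy as np
        object.__setattr__(self, "_pv", np.array(
            [getattr(self, name) for name in PARAM_ORDER], dtype=float))

    @property
    def vector(self):
        """Numeric parameter vector in :data:`PARAM_ORDER` (for kernels)."""
        return self._pv

    def replace(self, **overrides: float) -> "Parameters":
        """Return a copy with the given fields replaced."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict[str, Any], **overrides: float) -> "Parameters":
        merged = {**data, **overrides}
        return cls(**merged)

    @classmethod
    def from_json(cls, path: str | Path, **overrides: float) -> "Parameters":
        return cls.from_dict(json.loads(Path(path).read_text()), **overrides)


def default_parameter_file() -> Path:
    """Path of the bundled JSON file with the published default parameters."""
    return Path(str(resources.files("tcellca").joinpath("data/default_parameters.json")))


def load_parameters(V_PLC: float, delta: float, **overrides: float) -> Parameters:
    """Build a parameter set from the bundled defaults.

    ``V_PLC`` and ``delta`` are required; any other field may be overridden
    by keyword.
    """
    data = json.loads(default_parameter_file().read_text())
    return Parameters.from_dict(data, V_PLC=V_PLC, delta=delta, **overrides)
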