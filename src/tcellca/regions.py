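"""Regime occupancy maps and oscillatory-region intersections.

A regime map simulates the model on a grid in a two-parameter plane and
labels each cell with the classified waveform regime; it serves as ground
truth for the sidedness of Hopf curves and for locating the parameter
region where the CRAC-driven and IP₃R-driven oscillation families
coexist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .continuation import Codim2Curve
from .features import RegimeThresholds, extract_features
from .parameters import Parameters

__all__ = ["RegimeGrid", "region_map", "region_intersection_delta",
           "curve_envelope"]


@dataclass
class RegimeGrid:
    """Per-cell regime labels over a (p1, p2) grid."""

    model: str
    params: Parameters
    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    p2_values: np.ndarray
    labels: np.ndarray        # shape (len(p1), len(p2)), dtype object

    def cells(self, regime: str) -> list[tuple[float, float]]:
        out = []
        for i, a in enumerate(self.p1_values):
            for j, b in enumerate(self.p2_values):
                if self.labels[i, j] == regime:
                    out.append((float(a), float(b)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.p1_values):
            for j, b in enumerate(self.p2_values):
                rows.append({self.p1_name: a, self.p2_name: b,
                             "regime": self.labels[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def region_map(model: str, params: Parameters, p1_name: str, p1_grid,
               p2_name: str, p2_grid, *, t_end: float = 800.0,
               dt_out: float = 0.02, transient_fraction: float = 0.6,
               thresholds: RegimeThresholds = RegimeThresholds()) -> RegimeGrid:
    """Simulate and classify the regime in every cell of a parameter grid.

    Each cell starts from its own unstimulated (V_PLC = 0) equilibrium,
    mimicking a stimulation protocol. Failed integrations are labeled
    ``"failed"``.
    """
    from .simulate import integrate, unstimulated_equilibrium

    p1_grid = np.asarray(p1_grid, dtype=float)
    p2_grid = np.asarray(p2_grid, dtype=float)
    if p1_grid.size * p2_grid.size > 100 * 100:
        raise ValueError("grid larger than 100x100")
    labels = np.empty((p1_grid.size, p2_grid.size), dtype=object)
    for i, a in enumerate(p1_grid):
        for j, b in enumerate(p2_grid):
            p = params.replace(**{p1_name: float(a), p2_name: float(b)})
            try:
                init = unstimulated_equilibrium(model, p).state
                traj = integrate(model, p, init, t_end, dt_out)
                feats = extract_features(traj, p, transient_fraction,
                                         thresholds)
                labels[i, j] = feats.regime
            except Exception:
                labels[i, j] = "failed"
    return RegimeGrid(model, params, p1_name, p2_name, p1_grid, p2_grid,
                      labels)


def curve_envelope(curve: Codim2Curve, axis_name: str, sample_values,
                   which: str) -> np.ndarray:
    """Lower or upper envelope of a curve along one axis.

    For each sample of ``axis_name`` the polyline is intersected with the
    vertical line at that value and the min ('lower') or max ('upper') of
    the other coordinate is returned (nan where the curve does not reach).
    """
    if axis_name == curve.p1_name:
        x, y = curve.p1_values, curve.p2_values
    elif axis_name == curve.p2_name:
        x, y = curve.p2_values, curve.p1_values
    else:
        raise ValueError(f"{axis_name!r} is not an axis of this curve")
    sample_values = np.asarray(sample_values, dtype=float)
    out = np.full(sample_values.size, np.nan)
    for k, xv in enumerate(sample_values):
        hits = []
        for i in range(x.size - 1):
            x0, x1 = x[i], x[i + 1]
            if (x0 - xv) * (x1 - xv) <= 0 and x0 != x1:
                t = (xv - x0) / (x1 - x0)
                hits.append(y[i] + t * (y[i + 1] - y[i]))
        if hits:
            out[k] = min(hits) if which == "lower" else max(hits)
    return out


def region_intersection_delta(crac_curve: Codim2Curve,
                              spike_curve: Codim2Curve,
                              v_plc_grid: Optional[np.ndarray] = None
                              ) -> Optional[float]:
    """Smallest delta at which the two oscillatory regions overlap.

    The CRAC-driven oscillatory region lies above its Hopf curve in delta
    (lower envelope delta_lo(V_PLC)); the IP₃R-spike region lies below its
    Hopf curve (upper envelope delta_hi(V_PLC)). The regions intersect
    where delta_lo <= delta_hi; the first contact as delta grows is
    min delta_lo over that window. Returns None when the regions are
    disjoint. Both curves must live in a (delta, V_PLC) plane (either axis
    order).
    """
    def vname(curve):
        for nm in (curve.p1_name, curve.p2_name):
            if nm == "V_PLC":
                return nm
        raise ValueError("curve has no V_PLC axis")

    vname(crac_curve), vname(spike_curve)
    if v_plc_grid is None:
        vs = []
        for c in (crac_curve, spike_curve):
            v = c.p1_values if c.p1_name == "V_PLC" else c.p2_values
            vs.append((v.min(), v.max()))
        lo = max(v[0] for v in vs)
        hi = min(v[1] for v in vs)
        if hi <= lo:
            return None
        v_plc_grid = np.linspace(lo, hi, 400)
    d_lo = curve_envelope(crac_curve, "V_PLC", v_plc_grid, "lower")
    d_hi = curve_envelope(spike_curve, "V_PLC", v_plc_grid, "upper")
    ok = np.isfinite(d_lo) & np.isfinite(d_hi) & (d_lo <= d_hi)
    if not np.any(ok):
        return None
    return float(np.min(d_lo[ok]))
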