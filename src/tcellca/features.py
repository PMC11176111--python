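"""Oscillation feature extraction and waveform-based regime classification.

The model produces qualitatively distinct attractors — slow near-sinusoidal
CRAC-driven cycles, narrow IP₃R spikes, wide spikes, wide spikes carrying an
oscillatory plateau, and hybrid spike-on-CRAC orbits. The published
descriptions of these regimes are verbal, so classification here is by
explicit waveform rules whose thresholds are exposed in
:class:`RegimeThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .parameters import Parameters

__all__ = ["OscillationFeatures", "RegimeThresholds", "extract_features",
           "classify_regime", "count_transient_spikes"]

REGIMES = ("steady", "crac_sinusoidal", "narrow_spike", "wide_spike",
           "wide_spike_plateau", "hybrid", "other")


@dataclass(frozen=True)
class RegimeThresholds:
    """Tunable thresholds of the waveform classifier.

    Defaults: a trace is non-oscillating below 1e-3 µM peak-to-trough;
    spikes are counted at prominence ≥ 25% of the peak-to-trough range,
    principal spikes at 50%; narrow spikes occupy < 25% of the period above
    the midline; the CRAC cycle has a duty cycle in [0.4, 0.6] and requires
    visible store-operated influx (max s > 10% of V_SOCE); a plateau needs
    at least 2 secondary maxima per cycle on the elevated phase; a hybrid
    orbit is a spiking trace riding on a slowly oscillating influx
    (peak-to-trough of s > 10% of V_SOCE).
    """

    osc_eps: float = 1e-3
    spike_prominence: float = 0.25
    principal_prominence: float = 0.5
    secondary_prominence: float = 0.02
    duty_narrow: float = 0.25
    duty_crac_lo: float = 0.4
    duty_crac_hi: float = 0.6
    s_max_fraction_min: float = 0.1
    s_swing_hybrid: float = 0.1
    min_secondary_maxima: int = 2
    spike_width_frac: float = 0.25
    narrow_spike_max_width: float = 1.6   # base width, seconds
    transient_height_ratio: float = 1.15
    transient_max_width: float = 5.0


@dataclass
class OscillationFeatures:
    """Summary of a post-transient trajectory.

    ``period`` is the mean spacing of upward crossings of c through its
    midrange level; ``period_principal`` the mean spacing of the
    largest-amplitude spikes (identical for simple waveforms, the relevant
    notion for bursting ones). ``amplitude`` is the post-transient peak
    value of c; the peak-to-trough swing is kept alongside as
    ``amplitude_ptp`` since both readings are in use for this model.
    """

    oscillating: bool
    period: float
    period_principal: float
    c_max: float
    c_min: float
    amplitude: float
    amplitude_ptp: float
    ce_max: float
    ce_min: float
    er_depletion_per_cycle: float
    s_max_fraction: float
    s_swing_fraction: float
    duty_cycle: float
    n_secondary_maxima: float
    spike_width_fraction: float
    spike_width_base: float = float("nan")   # seconds, near the spike base
    regime: str = "other"

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        return d


def _upward_crossings(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Times of upward crossings of ``x`` through ``level`` (linear interp)."""
    below = x[:-1] < level
    above = x[1:] >= level
    idx = np.where(below & above)[0]
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def extract_features(traj, params: Optional[Parameters] = None,
                     transient_fraction: float = 0.5,
                     thresholds: RegimeThresholds = RegimeThresholds()) -> OscillationFeatures:
    """Post-transient oscillation features of a trajectory.

    The first ``transient_fraction`` of the run is discarded; the run
    should span many putative cycles for the period estimate to settle.
    """
    params = params or traj.params
    t0 = traj.times[0] + transient_fraction * (traj.times[-1] - traj.times[0])
    post = traj.after(t0)
    t, c = post.times, post.c
    ce = post.c_e
    s = post.s

    c_min, c_max = float(c.min()), float(c.max())
    ptp = c_max - c_min
    s_max_fraction = float(s.max() / params.V_SOCE) if s is not None else 0.0
    s_swing = float((s.max() - s.min()) / params.V_SOCE) if s is not None else 0.0

    oscillating = ptp >= thresholds.osc_eps
    period = period_pr = float("nan")
    duty = 0.0
    n_sec = 0.0
    width_frac = float("nan")
    if oscillating:
        mid = 0.5 * (c_min + c_max)
        crossings = _upward_crossings(t, c, mid)
        if crossings.size >= 2:
            period = float(np.diff(crossings).mean())
            duty = float(np.mean(c > mid))
        else:
            oscillating = False
        dt = float(np.median(np.diff(t)))
        pk, props = find_peaks(c, prominence=thresholds.principal_prominence * ptp,
                               width=1)
        width_base = float("nan")
        if pk.size >= 2:
            period_pr = float(np.diff(t[pk]).mean())
            width_frac = float(np.median(props["widths"]) * dt / period_pr)
            _, base_props = find_peaks(
                c, prominence=thresholds.principal_prominence * ptp,
                width=1, rel_height=0.8)
            width_base = float(np.median(base_props["widths"]) * dt)
            # secondary maxima on the elevated phase, per principal cycle
            elevated = c_min + 0.25 * ptp
            all_pk, _ = find_peaks(c, prominence=thresholds.secondary_prominence * ptp)
            n_elevated = int(np.sum(c[all_pk] > elevated))
            n_cycles = pk.size
            n_sec = max(0.0, (n_elevated - pk.size) / n_cycles)
        elif not np.isnan(period):
            period_pr = period
            width_base = float("nan")

    er_depl = float(ce.max() - ce.min()) if oscillating else 0.0

    feats = OscillationFeatures(
        oscillating=bool(oscillating),
        period=period,
        period_principal=period_pr,
        c_max=c_max, c_min=c_min,
        amplitude=c_max, amplitude_ptp=ptp,
        ce_max=float(ce.max()), ce_min=float(ce.min()),
        er_depletion_per_cycle=er_depl,
        s_max_fraction=s_max_fraction,
        s_swing_fraction=s_swing,
        duty_cycle=duty,
        n_secondary_maxima=n_sec,
        spike_width_fraction=width_frac,
        spike_width_base=width_base if oscillating else float("nan"),
    )
    feats.regime = classify_regime(feats, post, params, thresholds)
    return feats


def classify_regime(features: OscillationFeatures, traj=None,
                    params: Optional[Parameters] = None,
                    thresholds: RegimeThresholds = RegimeThresholds()) -> str:
    """Deterministic rule-based regime label for extracted features."""
    f, th = features, thresholds
    if not f.oscillating:
        return "steady"
    spiky = f.duty_cycle < th.duty_narrow or (
        not np.isnan(f.spike_width_fraction) and f.spike_width_fraction < th.spike_width_frac)
    if spiky and f.s_swing_fraction > th.s_swing_hybrid:
        return "hybrid"
    if (th.duty_crac_lo <= f.duty_cycle <= th.duty_crac_hi
            and f.s_max_fraction > th.s_max_fraction_min and not spiky):
        return "crac_sinusoidal"
    if f.n_secondary_maxima >= th.min_secondary_maxima:
        return "wide_spike_plateau"
    # narrow vs wide IP3R spikes separate by the absolute width of the
    # spike near its base (the duty cycle at the midline does not: the
    # broad spike is wide at the base but brief at half height)
    if np.isnan(f.spike_width_base):
        return "narrow_spike" if f.duty_cycle < th.duty_narrow else "wide_spike"
    if f.spike_width_base < th.narrow_spike_max_width:
        return "narrow_spike"
    return "wide_spike"


def count_transient_spikes(traj, features: OscillationFeatures,
                           thresholds: RegimeThresholds = RegimeThresholds()
                           ) -> tuple[int, float, np.ndarray]:
    """Sharp c-spikes before convergence to the final cycle.

    A transient spike is a peak that is both sharper (width below
    ``transient_max_width`` seconds) and higher (by
    ``transient_height_ratio``) than the converged cycle's maximum.
    Returns (count, duration since stimulus onset, spike times).
    """
    t, c = traj.times, traj.c
    dt = float(np.median(np.diff(t)))
    ptp = float(c.max() - c.min())
    if ptp < thresholds.osc_eps:
        return 0, 0.0, np.array([])
    pk, props = find_peaks(c, prominence=thresholds.spike_prominence * ptp, width=1)
    widths = props["widths"] * dt
    height_cut = features.c_max * thresholds.transient_height_ratio
    sharp = (widths < thresholds.transient_max_width) & (c[pk] > height_cut)
    times = t[pk[sharp]]
    if times.size == 0:
        return 0, 0.0, times
    duration = float(times[-1] - traj.times[0])
    return int(times.size), duration, times
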