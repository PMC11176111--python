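"""Scripted reproduction of the study's figure-level computations.

Each figure id maps to a pipeline that regenerates the underlying data
(trajectories, branches, curves, regime grids) with the published
parameter choices, writes them as CSV when an output directory is given,
and returns a JSON-serializable summary with the checkable quantities
(periods, amplitudes, detected bifurcations, region statistics).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import model as _m
from .continuation import continue_equilibria, continue_hopf_2par
from .features import extract_features
from .orbits import continue_periodic_orbits, orbit_from_simulation
from .parameters import Parameters
from .regions import region_intersection_delta, region_map
from .simulate import (integrate, run_fig7_scenario, unstimulated_equilibrium)

__all__ = ["ScenarioConfig", "reproduce", "FIGURE_IDS"]

log = logging.getLogger("tcellca.scenarios")

FIGURE_IDS = ("3A", "3B", "3C", "3D", "4", "5A", "5B", "5C", "5D", "5E",
              "5F", "6", "7", "8A", "8B", "8C", "8D", "8E", "8F", "9",
              "10", "11", "12")

SCHEMA_VERSION = 1

_PARAM_FIELDS = {f for f in Parameters(V_PLC=0, delta=0).to_dict()}


class ScenarioConfig(BaseModel):
    """Validated configuration of one figure pipeline."""

    figure_id: str
    overrides: dict[str, float] = Field(default_factory=dict)
    t_end: Optional[float] = None
    dt_out: float = 0.01
    quick: bool = False

    @field_validator("figure_id")
    @classmethod
    def _known_figure(cls, v: str) -> str:
        if v not in FIGURE_IDS:
            raise ValueError(f"unknown figure id {v!r}; expected one of {FIGURE_IDS}")
        return v

    @field_validator("overrides")
    @classmethod
    def _known_fields(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - _PARAM_FIELDS
        if unknown:
            raise ValueError(f"unknown parameter override(s): {sorted(unknown)}")
        return v


def _params(cfg: ScenarioConfig, V_PLC: float, delta: float, **kw) -> Parameters:
    kw = {**kw, **cfg.overrides}
    kw.setdefault("V_PLC", V_PLC)
    kw.setdefault("delta", delta)
    return Parameters(**kw)


def _sim_summary(model: str, params: Parameters, t_end: float,
                 cfg: ScenarioConfig, out: Optional[Path], tag: str) -> dict:
    init = unstimulated_equilibrium(model, params).state
    traj = integrate(model, params, init, t_end, cfg.dt_out)
    feats = extract_features(traj, params)
    if out:
        traj.to_csv(out / f"fig{tag}_trajectory.csv")
    d = feats.as_dict()
    d["t_end"] = t_end
    return d


def _fig3(panel: str):
    spec = {"3A": ("open", 0.1, 2.0, None, 800.0),
            "3B": ("closed", 0.1, 0.0, 140.0, 200.0),
            "3C": ("closed", 0.1, 0.0, 75.0, 400.0),
            "3D": ("closed", 0.195, 0.0, 95.0, 800.0)}[panel]

    def run(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
        model, vplc, delta, ct, t_end = spec
        kw = {} if ct is None else {"C_t": ct}
        p = _params(cfg, vplc, delta, **kw)
        return _sim_summary(model, p, cfg.t_end or t_end, cfg, out, panel)

    return run


def _eq_diag(model: str, par_name: str, par_range, p: Parameters,
             out: Optional[Path], tag: str) -> tuple[dict, Any]:
    eq0 = unstimulated_equilibrium(model, p.replace(
        **{par_name: par_range[0]} if par_name == "V_PLC" else {}))
    start = eq0.state
    branch = continue_equilibria(model, p, par_name, par_range, start)
    if out:
        branch.to_csv(out / f"fig{tag}_equilibria.csv")
    hbs = branch.hopf_points()
    summary = {
        "n_hopf": len(hbs),
        "hopf_" + par_name: [round(float(h.par_value), 6) for h in hbs],
        "n_saddle_node": len(branch.saddle_nodes()),
    }
    return summary, branch


def _po_diag(model: str, p: Parameters, branch, out, tag,
             quick: bool, par_range=None, seed_par: float | None = None,
             n_nodes: int = 30, max_steps: int = 140) -> dict:
    hbs = branch.hopf_points()
    par_name = branch.par_name
    if seed_par is None and len(hbs) >= 2:
        seed_par = 0.5 * (hbs[0].par_value + hbs[1].par_value)
    pr = par_range or (float(branch.par_values.min()),
                       float(branch.par_values.max()))
    orbit = orbit_from_simulation(model, p.replace(**{par_name: seed_par}),
                                  n_nodes=n_nodes)
    po = continue_periodic_orbits(model, p, par_name, orbit, pr,
                                  n_nodes=n_nodes,
                                  max_steps=60 if quick else max_steps)
    if out:
        po.to_csv(out / f"fig{tag}_orbits.csv")
    return {
        "po_par_min": float(po.par_values.min()),
        "po_par_max": float(po.par_values.max()),
        "n_snpo": len(po.detected("SNPO")),
        "n_pd": len(po.detected("PD")),
        "n_tr": len(po.detected("TR")),
        "snpo_" + par_name: [round(q.par_value, 6) for q in po.detected("SNPO")],
        "pd_" + par_name: [round(q.par_value, 6) for q in po.detected("PD")],
        "stable_fraction": float(np.mean(po.stable)),
        "period_range": [float(po.periods.min()), float(po.periods.max())],
    }


def _fig4(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    p = _params(cfg, 0.0, 2.0)
    summary, branch = _eq_diag("open", "V_PLC", (0.0, 0.3), p, out, "4")
    summary.update(_po_diag("open", p, branch, out, "4", cfg.quick))
    p_run = p.replace(V_PLC=0.1)
    traj = integrate("open", p_run, unstimulated_equilibrium("open", p_run).state,
                     cfg.t_end or 800.0, cfg.dt_out)
    feats = extract_features(traj, p_run)
    if out:
        traj.to_csv(out / "fig4_trajectory.csv")
    summary["traj_period"] = feats.period
    summary["traj_regime"] = feats.regime
    return summary


def _fig5_one_par(par_name: str, par_range):
    def run(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
        p = _params(cfg, 0.1, 2.0)
        # the V_PLC=0.1 equilibrium continued in the SOCE parameter
        from .simulate import stimulated_equilibrium
        start = stimulated_equilibrium("open", p).state
        branch = continue_equilibria("open", p, par_name, par_range, start)
        if out:
            branch.to_csv(out / f"fig5_{par_name}_equilibria.csv")
        hbs = branch.hopf_points()
        return {"n_hopf": len(hbs),
                "hopf_" + par_name: [round(float(h.par_value), 6) for h in hbs]}
    return run


def _fig5_two_par(p1_name: str, p2_name: str, box):
    def run(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
        p = _params(cfg, 0.1, 2.0)
        from .simulate import stimulated_equilibrium
        start = stimulated_equilibrium("open", p).state
        # localize a Hopf in p1 first
        branch = continue_equilibria("open", p, p1_name, box[p1_name], start)
        hbs = branch.hopf_points()
        if not hbs:
            return {"n_hopf": 0, "curve_points": 0}
        curve = continue_hopf_2par("open", p, p1_name, p2_name, hbs[0],
                                   box=box)
        if out:
            curve.to_csv(out / f"fig5_{p1_name}_{p2_name}_hopf.csv")
        return {"curve_points": int(curve.p1_values.size),
                "closed_curve": bool(curve.closed),
                f"min_{p1_name}": float(curve.p1_values.min()),
                f"max_{p1_name}": float(curve.p1_values.max()),
                f"min_{p2_name}": float(curve.p2_values.min()),
                f"max_{p2_name}": float(curve.p2_values.max())}
    return run


def _fig5e(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    p = _params(cfg, 0.1, 2.0)
    ce = np.linspace(700.0, 900.0, 401)
    soce = np.array([float(_m.j_soce(v, p)) for v in ce])
    hill_n = 100
    hill = p.V_SOCE * p.K_e**hill_n / (p.K_e**hill_n + ce**hill_n)
    if out:
        import pandas as pd
        pd.DataFrame({"c_e": ce, "J_SOCE": soce,
                      "reverse_hill_n100": hill}).to_csv(
            out / "fig5E_activation.csv", index=False)
    # steepness comparison at the midpoint
    mid_slope_soce = -p.s1 * p.V_SOCE / 4.0
    mid_slope_hill = -hill_n * p.V_SOCE / (4.0 * p.K_e)
    return {"midpoint_slope_soce": mid_slope_soce,
            "midpoint_slope_reverse_hill": mid_slope_hill,
            "slope_ratio": mid_slope_soce / mid_slope_hill}


def _fig6(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    # CRAC-mediated run
    p2 = _params(cfg, 0.1, 2.0)
    tr2 = integrate("open", p2, unstimulated_equilibrium("open", p2).state,
                    cfg.t_end or 800.0, cfg.dt_out)
    # narrow-spike run: no PM exchange, ER load of the C_t = 140 closed cell
    p0 = _params(cfg, 0.1, 0.0)
    eq_c = unstimulated_equilibrium("closed", p0.replace(C_t=140.0))
    c0, h0, _ = eq_c.state
    init0 = np.array([c0, p0.gamma * (140.0 - c0), h0, 0.0, 0.0])
    tr0 = integrate("open", p0, init0, 200.0, 0.002)
    half = lambda tr: tr.after(tr.times[0] + 0.5 * (tr.times[-1] - tr.times[0]))
    p0_crac = half(tr2).fluxes()["P0"].to_numpy()
    p0_spike = half(tr0).fluxes()["P0"].to_numpy()
    if out:
        half(tr2).fluxes().to_csv(out / "fig6_fluxes_crac.csv")
        half(tr0).fluxes().to_csv(out / "fig6_fluxes_spike.csv")
    ratio = float(p0_spike.max() / p0_crac.max())
    return {"max_P0_crac": float(p0_crac.max()),
            "max_P0_spike": float(p0_spike.max()),
            "P0_ratio_spike_over_crac": ratio}


def _fig7(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    p = _params(cfg, 0.0, 2.0)
    summary: dict[str, Any] = {}
    for ce0, tag in ((809.0, "low_load"), (850.0, "high_load")):
        traj, rep = run_fig7_scenario(ce0, p, t_end=cfg.t_end or 600.0,
                                      dt_out=cfg.dt_out)
        if out:
            traj.to_csv(out / f"fig7_{tag}_trajectory.csv")
        cyc = traj.after(traj.times[-1] - 3.0 * rep.cycle_period)
        summary[tag] = {
            "c_e_init": ce0, "c_init": float(traj.states[0, 0]),
            "s_init": float(traj.states[4, 0]),
            "n_transient_spikes": rep.n_spikes,
            "transient_duration": rep.duration,
            "cycle_period": rep.cycle_period,
            "cycle_ce_min": float(cyc.c_e.min()),
            "cycle_ce_max": float(cyc.c_e.max()),
        }
    return summary


def _fig8(panel: str):
    spec = {"8A": (140.0, "branch", None), "8B": (140.0, "traj", (0.1,)),
            "8C": (95.0, "branch", None), "8D": (95.0, "traj", (0.09, 0.195)),
            "8E": (75.0, "branch", None), "8F": (75.0, "traj", (0.06, 0.1))}[panel]

    def run(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
        ct, kind, vplcs = spec
        p = _params(cfg, 0.0, 0.0, C_t=ct)
        if kind == "traj":
            summary = {}
            for v in vplcs:
                pv = p.replace(V_PLC=v)
                summary[f"V_PLC={v}"] = _sim_summary(
                    "closed", pv, cfg.t_end or 600.0, cfg, out,
                    f"{panel}_vplc{v}")
            return summary
        summary, branch = _eq_diag("closed", "V_PLC", (0.0, 0.6), p, out, panel)
        hbs = branch.hopf_points()
        seed = {140.0: 0.1, 95.0: 0.09, 75.0: 0.06}[ct]
        summary.update(_po_diag("closed", p, branch, out, panel, cfg.quick,
                                par_range=(0.0, 0.6), seed_par=seed))
        return summary

    return run


def _fig9(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    p = _params(cfg, 0.0, 0.0, C_t=95.0)
    summary, branch = _eq_diag("closed", "V_PLC", (0.0, 0.6), p, None, "9")
    hbs = branch.hopf_points()
    curve = continue_hopf_2par("closed", p, "V_PLC", "C_t", hbs[0],
                               box={"V_PLC": (0.005, 0.8), "C_t": (40.0, 200.0)})
    if out:
        curve.to_csv(out / "fig9_hopf_curve.csv")
    pd_pts, snpo_pts, tr_pts = [], [], []
    ct_grid = (95.0, 85.0, 75.0) if not cfg.quick else (95.0,)
    for ct in ct_grid:
        pc = p.replace(C_t=ct)
        s2, br = _eq_diag("closed", "V_PLC", (0.0, 0.6), pc, None, "9")
        d = _po_diag("closed", pc, br, None, "9", cfg.quick,
                     par_range=(0.0, 0.6),
                     seed_par={95.0: 0.09, 85.0: 0.08, 75.0: 0.06}[ct])
        pd_pts += [(v, ct) for v in d["pd_V_PLC"]]
        snpo_pts += [(v, ct) for v in d["snpo_V_PLC"]]
        # the isolated plateau branch, located by simulation near the right HB
        try:
            plateau_v = {95.0: 0.195, 85.0: 0.16, 75.0: 0.1}[ct]
            orb = orbit_from_simulation("closed", pc.replace(V_PLC=plateau_v),
                                        n_nodes=40)
            po = continue_periodic_orbits("closed", pc, "V_PLC", orb,
                                          (0.02, 0.6), n_nodes=40,
                                          max_steps=30 if cfg.quick else 80)
            tr_pts += [(q.par_value, ct) for q in po.detected("TR")]
        except Exception as exc:     # plateau branch may not exist at this C_t
            log.info("fig9: plateau branch at C_t=%s not continued: %s", ct, exc)
    if out:
        import pandas as pd
        for nm, pts in (("pd", pd_pts), ("snpo", snpo_pts), ("tr", tr_pts)):
            pd.DataFrame(pts, columns=["V_PLC", "C_t"]).to_csv(
                out / f"fig9_{nm}_points.csv", index=False)
    summary.update({
        "hb_curve_points": int(curve.p1_values.size),
        "n_pd_points": len(pd_pts), "n_snpo_points": len(snpo_pts),
        "n_tr_points": len(tr_pts),
        "curves_present": {"HB": curve.p1_values.size > 0,
                           "PD": len(pd_pts) > 0,
                           "SNPO": len(snpo_pts) > 0,
                           "TR": len(tr_pts) > 0},
    })
    return summary


def _fig10(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    summary = {}
    for delta, tag in ((2.0, "crac"), (0.01, "ipr")):
        p = _params(cfg, 0.0, delta)
        s, branch = _eq_diag("open", "V_PLC", (0.0, 0.3), p, out,
                             f"10_{tag}")
        p_run = p.replace(V_PLC=0.1)
        traj = integrate("open", p_run,
                         unstimulated_equilibrium("open", p_run).state,
                         cfg.t_end or 800.0, cfg.dt_out)
        feats = extract_features(traj, p_run)
        if out:
            traj.to_csv(out / f"fig10_{tag}_trajectory.csv")
        s.update({"period": feats.period_principal, "regime": feats.regime,
                  "er_depletion": feats.er_depletion_per_cycle})
        summary[tag] = s
    return summary


def _delta_vplc_curves(cfg: ScenarioConfig, K_e: float, out, tag) -> dict:
    """Two Hopf-curve families in the (delta, V_PLC) plane."""
    from .simulate import find_equilibrium
    box = {"delta": (1e-3, 4.0), "V_PLC": (0.005, 0.6)}
    curves = {}
    for delta, fam in ((2.0, "crac"), (0.01, "spike")):
        p = _params(cfg, 0.0, delta, K_e=K_e)
        start = unstimulated_equilibrium("open", p).state
        branch = continue_equilibria("open", p, "V_PLC", (0.0, 0.6), start)
        hbs = branch.hopf_points()
        if not hbs:
            curves[fam] = None
            continue
        curves[fam] = continue_hopf_2par("open", p, "V_PLC", "delta",
                                         hbs[0], box=box)
        if out:
            curves[fam].to_csv(out / f"fig{tag}_{fam}_hopf.csv")
    summary = {}
    for fam, c in curves.items():
        if c is None:
            summary[fam] = {"present": False}
        else:
            summary[fam] = {"present": True,
                            "delta_range": [float(c.p2_values.min()),
                                            float(c.p2_values.max())],
                            "V_PLC_range": [float(c.p1_values.min()),
                                            float(c.p1_values.max())],
                            "points": int(c.p1_values.size)}
    if curves.get("crac") is not None and curves.get("spike") is not None:
        summary["intersection_delta"] = region_intersection_delta(
            curves["crac"], curves["spike"])
    return summary


def _fig11(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    return _delta_vplc_curves(cfg, 800.0, out, "11")


def _fig12(cfg: ScenarioConfig, out: Optional[Path]) -> dict:
    summary = _delta_vplc_curves(cfg, 400.0, out, "12")
    # the hybrid orbit at the published in-text parameter point
    p = _params(cfg, 0.1, 0.62, K_e=400.0)
    traj = integrate("open", p, unstimulated_equilibrium("open", p).state,
                     cfg.t_end or 1500.0, cfg.dt_out)
    feats = extract_features(traj, p)
    summary["hybrid_point"] = {"delta": 0.62, "V_PLC": 0.1, "K_e": 400.0,
                               "regime": feats.regime,
                               "period": feats.period_principal}
    return summary


_REGISTRY: dict[str, Callable[[ScenarioConfig, Optional[Path]], dict]] = {
    "3A": _fig3("3A"), "3B": _fig3("3B"), "3C": _fig3("3C"), "3D": _fig3("3D"),
    "4": _fig4,
    "5A": _fig5_one_par("s1", (0.12, 0.35)),
    "5B": _fig5_two_par("s1", "V_PLC", {"s1": (0.05, 0.6),
                                        "V_PLC": (0.005, 0.6)}),
    "5C": _fig5_one_par("tau_s", (1.0, 120.0)),
    "5D": _fig5_two_par("tau_s", "V_PLC", {"tau_s": (0.5, 200.0),
                                           "V_PLC": (0.005, 0.6)}),
    "5E": _fig5e,
    "5F": _fig5_two_par("s1", "tau_s", {"s1": (0.05, 0.6),
                                        "tau_s": (0.5, 200.0)}),
    "6": _fig6, "7": _fig7,
    "8A": _fig8("8A"), "8B": _fig8("8B"), "8C": _fig8("8C"),
    "8D": _fig8("8D"), "8E": _fig8("8E"), "8F": _fig8("8F"),
    "9": _fig9, "10": _fig10, "11": _fig11, "12": _fig12,
}


def reproduce(figure_id: str, config: Optional[ScenarioConfig] = None,
              out_dir: Optional[str | Path] = None) -> dict:
    """Regenerate one figure's data; returns the summary dictionary."""
    cfg = config or ScenarioConfig(figure_id=figure_id)
    if cfg.figure_id != figure_id:
        raise ValueError("config.figure_id does not match figure_id")
    out = Path(out_dir) if out_dir is not None else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log.info("reproducing figure %s (overrides=%s)", figure_id, cfg.overrides)
    try:
        summary = _REGISTRY[figure_id](cfg, out)
    except Exception:
        log.exception("figure %s failed", figure_id)
        raise
    result = {"schema_version": SCHEMA_VERSION, "figure_id": figure_id,
              "overrides": cfg.overrides, "summary": summary}
    if out:
        (out / f"fig{figure_id}_summary.json").write_text(
            json.dumps(result, indent=2, default=float) + "\n")
    return result
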