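"""Waveform feature extraction and regime classification."""

import numpy as np

import tcellca as t
from tcellca.features import RegimeThresholds, classify_regime


def test_archetype_regimes(fig3_runs):
    expected = {"3A": "crac_sinusoidal", "3B": "narrow_spike",
                "3C": "wide_spike", "3D": "wide_spike_plateau"}
    for panel, regime in expected.items():
        _, _, _, feats = fig3_runs[panel]
        assert feats.regime == regime, f"panel {panel}: got {feats.regime}"


def test_amplitude_definitions_are_both_reported(fig3_runs):
    _, _, _, feats = fig3_runs["3A"]
    assert feats.amplitude == feats.c_max
    assert feats.amplitude_ptp == feats.c_max - feats.c_min
    assert feats.c_min <= feats.c_max


def test_er_depletion_nonnegative_and_consistent(fig3_runs):
    for panel in fig3_runs:
        _, _, _, feats = fig3_runs[panel]
        assert feats.er_depletion_per_cycle >= 0
        assert feats.er_depletion_per_cycle == feats.ce_max - feats.ce_min


def test_hybrid_rule_requires_slow_influx_modulation(fig3_runs):
    # the CRAC cycle modulates s strongly but is not spiking; the
    # narrow-spike closed cell has no s at all
    _, _, _, f_a = fig3_runs["3A"]
    assert f_a.s_swing_fraction > 0.1 and f_a.regime != "hybrid"
    _, _, _, f_b = fig3_runs["3B"]
    assert f_b.s_max_fraction == 0.0


def test_thresholds_are_configurable(fig3_runs):
    _, params, traj, _ = fig3_runs["3B"]
    th = RegimeThresholds(narrow_spike_max_width=0.1)
    feats = t.extract_features(traj, params, thresholds=th)
    # with an absurdly small narrow-spike width bound the same waveform
    # classifies as a wide spike
    assert feats.regime == "wide_spike"
    assert classify_regime(feats, thresholds=RegimeThresholds()) == "narrow_spike"


def test_crac_cycle_suppresses_fast_cicr(fig3_runs):
    # the IP3R open probability fires in sharp pulses during a narrow
    # spike (fast CICR) but stays a smooth low wave during the CRAC cycle
    _, _, traj_a, _ = fig3_runs["3A"]
    _, _, traj_b, _ = fig3_runs["3B"]
    half = lambda tr: tr.after(tr.times[0] + 0.5 * (tr.times[-1] - tr.times[0]))
    p0_crac = half(traj_a).fluxes()["P0"].to_numpy()
    p0_spike = half(traj_b).fluxes()["P0"].to_numpy()
    assert p0_spike.max() / np.median(p0_spike) > 3.0
    assert p0_crac.max() / np.median(p0_crac) < 2.0
    assert p0_spike.max() > p0_crac.max()


def test_transient_spike_detection(fig7_runs):
    _, rep_low = fig7_runs[809.0]
    _, rep_high = fig7_runs[850.0]
    assert rep_low.n_spikes == 0
    assert rep_high.n_spikes > 0
    assert rep_high.spike_times.size == rep_high.n_spikes
    assert rep_high.duration > 0
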