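"""Scenario configs, figure pipelines and the command-line layer."""

import json

import pytest

from tcellca.scenarios import ScenarioConfig, reproduce


class TestConfigValidation:
    def test_unknown_figure_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(figure_id="99Z")

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(figure_id="3A", overrides={"not_a_param": 1.0})

    def test_valid_config(self):
        cfg = ScenarioConfig(figure_id="3A", overrides={"K_e": 400.0})
        assert cfg.overrides["K_e"] == 400.0


class TestReproduce:
    def test_narrow_spike_panel_regression(self, tmp_path):
        """Pin the narrow-spike archetype's features."""
        r = reproduce("3B", out_dir=tmp_path)
        s = r["summary"]
        assert s["regime"] == "narrow_spike"
        assert abs(s["period"] - 2.91) < 0.05
        assert abs(s["c_max"] - 0.218) < 0.01
        assert (tmp_path / "fig3B_summary.json").exists()
        assert (tmp_path / "fig3B_trajectory.csv").exists()

    def test_rerun_is_bitwise_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        reproduce("3B", out_dir=a)
        reproduce("3B", out_dir=b)
        assert (a / "fig3B_trajectory.csv").read_bytes() == \
               (b / "fig3B_trajectory.csv").read_bytes()
        assert json.loads((a / "fig3B_summary.json").read_text()) == \
               json.loads((b / "fig3B_summary.json").read_text())

    def test_summary_schema_is_versioned(self):
        r = reproduce("5E")
        assert r["schema_version"] == 1
        assert r["figure_id"] == "5E"
        assert "slope_ratio" in r["summary"]


class TestCLI:
    def test_simulate_subcommand(self, tmp_path):
        from typer.testing import CliRunner
        from tcellca.cli import app
        out = tmp_path / "traj.csv"
        feats = tmp_path / "feats.json"
        res = CliRunner().invoke(app, [
            "simulate", "--model", "closed", "--set", "V_PLC=0.1",
            "--set", "C_t=140", "--set", "delta=0", "--t-end", "100",
            "--out", str(out), "--features", str(feats)])
        assert res.exit_code == 0, res.output
        payload = json.loads(feats.read_text())
        assert payload["regime"] == "narrow_spike"
        assert out.exists()
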