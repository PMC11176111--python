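"""Parameter validation and serialization."""

import numpy as np
import pytest

import tcellca as t
from tcellca.parameters import PARAM_ORDER, default_parameter_file


def test_bundled_defaults_round_trip(tmp_path):
    p = t.load_parameters(V_PLC=0.1, delta=2.0)
    assert p == t.Parameters(V_PLC=0.1, delta=2.0)
    out = tmp_path / "p.json"
    p.to_json(out)
    assert t.Parameters.from_json(out) == p
    assert default_parameter_file().exists()


def test_override_and_vector():
    p = t.Parameters(V_PLC=0.1, delta=2.0).replace(K_e=400.0)
    assert p.K_e == 400.0
    assert p.vector[PARAM_ORDER.index("K_e")] == 400.0
    assert np.all(p.vector == np.array([getattr(p, n) for n in PARAM_ORDER]))


@pytest.mark.parametrize("bad", [
    {"V_PLC": -0.1, "delta": 2.0},
    {"V_PLC": 0.1, "delta": -1.0},
    {"V_PLC": 0.1, "delta": 2.0, "gamma": 0.0},
    {"V_PLC": 0.1, "delta": 2.0, "tau_s": -3.0},
    {"V_PLC": 0.1, "delta": 2.0, "K_bar": -1e-9},
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ValueError):
        t.Parameters(**bad)


def test_unknown_replace_key_rejected():
    with pytest.raises(KeyError):
        t.Parameters(V_PLC=0.1, delta=2.0).replace(not_a_field=1.0)
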