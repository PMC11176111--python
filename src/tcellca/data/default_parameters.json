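{
  "gamma": 5.5,
  "V_PM": 3.0,
  "K_PM": 0.2,
  "V_SOCE": 3.0,
  "s1": 0.2,
  "K_e": 800.0,
  "tau_s": 15.0,
  "V_SERCA": 2.0,
  "K_SERCA": 0.19,
  "K_bar": 1e-08,
  "k_f": 1.6,
  "k_beta": 0.4,
  "K_p": 10.0,
  "K_c": 0.16,
  "K_h": 0.168,
  "tau_max": 7.5,
  "K_tau": 0.095,
  "tau_p": 2.0,
  "V_deg": 6.0,
  "K_deg": 0.5,
  "C_t": 140.0
}
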