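{
  "kg": 0.44,
  "kk": 0.3,
  "alpha": 0.06,
  "gamma1": 0.027,
  "gamma2": 0.044,
  "gamma3": 0.02,
  "v0_1": 26.0,
  "v0_2": 44.0,
  "v0_3": 22.0,
  "a_Rs1": 0.65,
  "a_Rs2": 0.2,
  "a_Rs3": 0.14,
  "b_Rs1": 0.26,
  "b_Rs2": 0.4,
  "b_Rs3": 0.16,
  "omega_gamma": 0.64,
  "omega_alpha": 0.5,
  "omega_v0": 0.4,
  "sigma_prop": 0.35,
  "sigma_add": 4.4,
  "alpha_beta_ratio": 10.0,
  "dose_scale": 10.0,
  "inhibition_kind": "linear"
}
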