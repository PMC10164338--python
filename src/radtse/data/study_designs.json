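{
  "studies": [
    {
      "study": 1,
      "weeks": 6,
      "fraction_dose_gy": 2.0,
      "observation_horizon_day": 84,
      "arms": [
        {"name": "vehicle", "compound": null, "dose_mg_kg": 0, "cmax_ug_ml": 0.0, "n_subjects": 9, "radiation": false, "observation_horizon_day": 24},
        {"name": "rt", "compound": null, "dose_mg_kg": 0, "cmax_ug_ml": 0.0, "n_subjects": 9, "radiation": true},
        {"name": "rt_rs1_100", "compound": "Rs1", "dose_mg_kg": 100, "cmax_ug_ml": 1.0, "n_subjects": 9, "radiation": true},
        {"name": "rt_rs2_25", "compound": "Rs2", "dose_mg_kg": 25, "cmax_ug_ml": 2.0, "n_subjects": 9, "radiation": true},
        {"name": "rt_rs2_100", "compound": "Rs2", "dose_mg_kg": 100, "cmax_ug_ml": 5.0, "n_subjects": 9, "radiation": true},
        {"name": "rt_rs3_20", "compound": "Rs3", "dose_mg_kg": 20, "cmax_ug_ml": 7.0, "n_subjects": 9, "radiation": true}
      ]
    },
    {
      "study": 2,
      "weeks": 1,
      "fraction_dose_gy": 2.0,
      "observation_horizon_day": 42,
      "arms": [
        {"name": "vehicle", "compound": null, "dose_mg_kg": 0, "cmax_ug_ml": 0.0, "n_subjects": 10, "radiation": false, "observation_horizon_day": 24},
        {"name": "rt", "compound": null, "dose_mg_kg": 0, "cmax_ug_ml": 0.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_10", "compound": "Rs1", "dose_mg_kg": 10, "cmax_ug_ml": 1.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_50", "compound": "Rs1", "dose_mg_kg": 50, "cmax_ug_ml": 2.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_200", "compound": "Rs1", "dose_mg_kg": 200, "cmax_ug_ml": 9.0, "n_subjects": 10, "radiation": true, "observation_horizon_day": 120}
      ]
    },
    {
      "study": 3,
      "weeks": 6,
      "fraction_dose_gy": 2.0,
      "observation_horizon_day": 84,
      "arms": [
        {"name": "rt", "compound": null, "dose_mg_kg": 0, "cmax_ug_ml": 0.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_25", "compound": "Rs1", "dose_mg_kg": 25, "cmax_ug_ml": 5.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_50", "compound": "Rs1", "dose_mg_kg": 50, "cmax_ug_ml": 6.0, "n_subjects": 10, "radiation": true},
        {"name": "rt_rs1_100", "compound": "Rs1", "dose_mg_kg": 100, "cmax_ug_ml": 7.0, "n_subjects": 10, "radiation": true}
      ]
    }
  ]
}
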