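{
  "corr_neuron_ictal": -0.002668,
  "corr_neuron_interictal": 0.012052,
  "corr_neuropil_ictal": 0.058101,
  "corr_neuropil_interictal": 0.407889,
  "deconv_agreement": 0.96,
  "frac_ictal_high": 0.0,
  "frac_ictal_low": 0.56,
  "frac_neutral": 0.44,
  "frac_participants_offset": 0.0,
  "frac_participants_onset": 0.030303,
  "frac_quiet": 0.137931,
  "mean_ictal_dff_pct": 2.968542,
  "mean_interictal_dff_pct": 5.811481,
  "n_neurons": 29,
  "n_rois": 33,
  "n_seizures": 6,
  "session_id": "sim-seed0"
}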