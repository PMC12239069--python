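{
  "name": "replication_5nm",
  "seed": 42,
  "field": {
    "surface_field_T": 0.27,
    "decay_length_m": 0.003,
    "origin_m": 0.0
  },
  "capsule": {
    "diameter_m": 0.00019,
    "np_diameter_m": 5e-09,
    "loading_ppm": 500,
    "intrinsic_susceptibility": 0.1062756208,
    "np_density_kg_m3": 5180.0,
    "matrix_density_kg_m3": 965.0,
    "demag_factor": 0.3333333333333333
  },
  "fluid": {
    "viscosity_Pa_s": 0.00089,
    "susceptibility": 0.0,
    "density_kg_m3": 997.0
  },
  "design": {
    "n_tracks": 12,
    "frame_rate_fps": 24.0,
    "duration_s": 60.0,
    "field_of_view_m": [
      0.006,
      0.002
    ],
    "start_x_min_m": 0.0005,
    "start_x_max_m": 0.005,
    "start_sampler": "stratified",
    "localization_noise_sd_m": 5e-07,
    "detection_dropout_prob": 0.0
  },
  "analysis": {
    "bin_width_m": 0.0001,
    "window_min_m": 0.0005,
    "window_max_m": 0.005,
    "max_gap_frames": 2
  },
  "calibration": {
    "target_mean_speed_m_s": 8e-05,
    "average": "observed",
    "note": "intrinsic_susceptibility is calibrated (not measured): chosen so the expected pooled frame-sampled mean approach speed over the analysis window equals target_mean_speed_m_s; decay_length_m = 3 mm is an assumed value typical of mm-scale NdFeB magnets."
  }
}
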