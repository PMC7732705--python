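# Synthetic cohort configuration (all keys optional; defaults shown).
n_surfaces: 30
crown_size_mm: 10.0
crown_radial_segments: 40
crown_angular_segments: 144
crown_wall_segments: 30
lesion_count_range: [1, 3]
lesion_amp_median_mm: 0.19
lesion_amp_sigma_log: 0.5
lesion_sigma_range_mm: [0.5, 0.8]
lesion_center_radius_mm: 1.0
reference_wear_depth_um_range: [30.0, 80.0]
max_pose_angle_deg: 5.0
max_pose_translation_mm: 2.0
profilometer:
  capture_model: profilometer
  step_um: 50.0
  noise_sd_um: 2.6
intraoral:
  capture_model: intraoral
  noise_sd_um: 5.0
  smoothing_iterations: 10
  smoothing_lambda: 0.5
  remesh_edge_mm: 0.2
seed: 0
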