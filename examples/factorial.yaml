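# Factorial experiment configuration. The cohort block mirrors cohort.yaml;
# this example is scaled down (coarser meshes, 100 um raster, fewer ICP
# samples) so a full run finishes in a couple of minutes on one CPU.
cohort:
  n_surfaces: 12
  crown_radial_segments: 28
  crown_angular_segments: 96
  crown_wall_segments: 20
  profilometer:
    capture_model: profilometer
    step_um: 100.0
    noise_sd_um: 2.6
  intraoral:
    capture_model: intraoral
    noise_sd_um: 5.0
  seed: 1
alignment:
  coarse_sample_n: 600
  fine_sample_n: 2000
  inlier_threshold_um: 25.0
  metric: point_to_plane
family_alpha: 0.05
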