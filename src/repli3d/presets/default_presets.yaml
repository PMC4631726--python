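E:
  stage: E
  cycle: mitotic
  target_volume_um3: 448.0
  volume_sd_um3: 44.0
  edu_mode: inter_fiber
  grid_shape:
  - 80
  - 168
  - 168
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.0315
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.7969
  com_displacement_um: 0.3038
  n_foci: 1500
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 4
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
M:
  stage: M
  cycle: mitotic
  target_volume_um3: 605.0
  volume_sd_um3: 61.0
  edu_mode: on_fiber
  grid_shape:
  - 80
  - 168
  - 168
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.0747
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.875
  com_displacement_um: 0.2363
  n_foci: 1500
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 4
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
L:
  stage: L
  cycle: mitotic
  target_volume_um3: 637.0
  volume_sd_um3: 83.0
  edu_mode: heterochromatin
  grid_shape:
  - 88
  - 176
  - 176
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.0699
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.0
  com_displacement_um: 0.0
  n_foci: 150
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 0
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
En-E:
  stage: En-E
  cycle: endocycle
  target_volume_um3: 742.0
  volume_sd_um3: 58.0
  edu_mode: inter_fiber
  grid_shape:
  - 88
  - 176
  - 176
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.0668
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.8438
  com_displacement_um: 0.5391
  n_foci: 1500
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 4
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
En-M:
  stage: En-M
  cycle: endocycle
  target_volume_um3: 826.0
  volume_sd_um3: 72.0
  edu_mode: on_fiber
  grid_shape:
  - 88
  - 176
  - 176
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.0500253966893347
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.90625
  com_displacement_um: 0.5175000000000001
  n_foci: 1500
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 4
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
En-L:
  stage: En-L
  cycle: endocycle
  target_volume_um3: 861.0
  volume_sd_um3: 36.0
  edu_mode: heterochromatin
  grid_shape:
  - 88
  - 176
  - 176
  voxel_size_um:
  - 0.2
  - 0.07
  - 0.07
  volume_factor: 1.064931048498484
  z_aspect: 1.25
  axis_jitter: 0.05
  center_jitter_um: 0.15
  nucleolus_radius_fraction: 0.24
  knob_radii_um:
  - 0.55
  - 0.55
  - 0.35
  - 0.35
  knob_intensity: 2.2
  fiber_n_walks: 48
  fiber_step_um: 0.06
  fiber_persistence: 0.85
  fiber_thickness_um: 0.3
  fiber_volume_fraction: 0.3
  fiber_amplitude: 1.5
  dapi_diffuse: 0.85
  coupling: 0.0
  com_displacement_um: 0.0
  n_foci: 150
  focus_sigma_um: 0.1
  foci_amp_sigma: 0.5
  edu_diffuse_fraction: 0.12
  intranucleolar_puncta_count: 0
  intranucleolar_puncta_amplitude: 0.6
  knob_margin_um: 0.15
  psf_sigma_um:
  - 0.3
  - 0.13
  - 0.13
  dapi_mean_counts: 1200.0
  edu_mean_counts: 350.0
  noise_gain: 2.0
  noise_read_sd: 4.0
  background: 20.0
  render_fish: false
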