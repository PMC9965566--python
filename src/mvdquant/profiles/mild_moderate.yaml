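name: mild_moderate
n_eyes: 110
size_px: 400
pixel_pitch_um: 11.25
disc_radius_px_mean: 55.0
disc_radius_px_sd: 4.0
disc_center_jitter_px: 8.0
se:
  target_mean: -2.51
  sd: 2.1
  lo: -6.0
  hi: -0.5
  loc: -1.538107
age:
  target_mean: 32.3
  sd: 12.84
  lo: 18.0
  hi: 40.0
  loc: 44.780273
female_prob: 0.282
al_mean: 24.36
al_se_slope: -0.35
al_noise_sd: 1.053275
beta_loc_mm2: -1.25889
beta_sd_mm2: 0.94204
beta_se_slope: -0.00287
beta_al_slope: 0.09769
beta_lo_mm2: 0.15
beta_hi_mm2: 2.5
alpha_presence_prob: 0.6
alpha_area_mean_mm2: 0.235
alpha_area_sd_mm2: 0.122
alpha_lo_mm2: 0.08
alpha_hi_mm2: 1.2
mvd_presence_prob: 0.91732
mvd_coupling_coeff: 0.245358
mvd_coupling_power: 2.50399
mvd_noise_cv: 0.21135
mvd_min_area_px: 21
mvd_max_frac_of_beta: 0.35
mvd_extra_region_lambda: 0.8
mvd_grey_mean: 30.0
mvd_grey_sd: 8.0
alpha_mvd_prob: 0.37
alpha_mvd_area_mean_mm2: 0.089
alpha_mvd_area_sd_mm2: 0.06
background_mean_grey: 160.0
background_speckle_sd: 25.0
background_floor_grey: 60.0
background_correlation_length_px: 2.0
vessel_n_trees: 4
vessel_width_px:
- 4.0
- 8.0
vessel_grey:
- 200.0
- 240.0
vessel_steps: 220
disc_grey: 25.0
quality_score_lo: 6
quality_score_hi: 10
artifact_prob: 0.0
seed: null
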