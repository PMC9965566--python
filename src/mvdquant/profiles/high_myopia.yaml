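name: high_myopia
n_eyes: 95
size_px: 400
pixel_pitch_um: 11.25
disc_radius_px_mean: 55.0
disc_radius_px_sd: 4.0
disc_center_jitter_px: 8.0
se:
  target_mean: -7.14
  sd: 0.927
  lo: -10.0
  hi: -6.0
  loc: -6.842019
age:
  target_mean: 36.21
  sd: 14.28
  lo: 18.0
  hi: 40.0
  loc: 86.143075
female_prob: 0.337
al_mean: 26.65
al_se_slope: -0.35
al_noise_sd: 0.843454
beta_loc_mm2: 1.221
beta_sd_mm2: 0.18
beta_se_slope: -0.00287
beta_al_slope: 0.09769
beta_lo_mm2: 0.15
beta_hi_mm2: 3.5
alpha_presence_prob: 0.8
alpha_area_mean_mm2: 0.336
alpha_area_sd_mm2: 0.188
alpha_lo_mm2: 0.08
alpha_hi_mm2: 1.2
mvd_presence_prob: 0.99
mvd_coupling_coeff: 0.142896
mvd_coupling_power: 2.50399
mvd_noise_cv: 0.21135
mvd_min_area_px: 21
mvd_max_frac_of_beta: 0.35
mvd_extra_region_lambda: 0.8
mvd_grey_mean: 30.0
mvd_grey_sd: 8.0
alpha_mvd_prob: 0.7
alpha_mvd_area_mean_mm2: 0.068
alpha_mvd_area_sd_mm2: 0.05
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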