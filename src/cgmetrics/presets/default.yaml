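# Default two-cohort study configuration.
#
# The cohort archetypes below are calibrated so that the full pipeline
# (simulate -> 15-min grid -> days 2-14 window -> index engine) reproduces
# the cohort-level days 2-14 summaries of a 53 healthy + 52 pre-diabetic
# CGM benchmarking study: mean glucose 102.4 / 112.2 mg/dL, GV-SD
# 16.2 / 19.4 mg/dL, GV-CV 15.8 / 17.3 %, TIR 95.3 / 94.6 %,
# TAR 0.1 / 1.4 %, TBR 1.6 / 1.0 %, MAGE 30.7 / 32.9 mg/dL
# (healthy / pre-diabetic).  Edit a copy of this file rather than the
# values here.

n_healthy: 53
n_prediabetic: 52
days: 14
interval_min: 15
rng_seed: 0

healthy:
  baseline_mean: 95.2
  baseline_sd: 10.0
  baseline_latent_weight: 0.6
  day_effect_sd: 3.0
  baseline_drift_per_day: -0.45
  circadian_amp: 9.0
  circadian_peak_hour: 16.0
  meal_hours: [8.0, 13.0, 20.0]
  meal_jitter_sd_min: 25.0
  meal_amp_median: 36.0
  meal_amp_sigma: 0.35
  meal_rise_min: 40.0
  meal_decay_min: 70.0
  amp_latent_coupling: 0.25
  amp_drift_per_day: -0.012
  noise_sd: 9.0
  noise_rho: 0.8
  biomarker_loading: 0.15
  target_r: 0.1
  biomarkers:
    fbg_mean: 90.5
    fbg_sd: 6.0
    fbg_lo: 79.0
    fbg_hi: 99.0
    fbg_end_shift: 1.8
    fbg_end_noise_sd: 4.0
    hba1c_mean: 5.2
    hba1c_sd: 0.3
    hba1c_lo: 4.0
    hba1c_hi: 5.6
    ogtt_mean: 115.0
    ogtt_sd: 14.0
    ogtt_lo: 70.0
    ogtt_hi: 139.0
    insulin_median: 6.5
    insulin_sigma: 0.35
    hscrp_median: 1.2
    hscrp_sigma: 0.6
    cortisol_mean: 12.0
    cortisol_sd: 3.0
  activity:
    steps_mean: 8000.0
    steps_subject_sd: 1800.0
    steps_day_sd: 1500.0
    steps_z_coupling: -300.0
    hr_mean: 72.0
    hr_subject_sd: 5.0
    hr_day_sd: 2.0
    hr_z_coupling: 1.0
    sleep_mean: 420.0
    sleep_subject_sd: 35.0
    sleep_day_sd: 30.0
    sleep_z_coupling: -5.0

prediabetic:
  baseline_mean: 103.2
  baseline_sd: 11.0
  baseline_latent_weight: 0.6
  day_effect_sd: 3.5
  baseline_drift_per_day: -0.6
  circadian_amp: 9.5
  circadian_peak_hour: 16.0
  meal_hours: [8.0, 13.0, 20.0]
  meal_jitter_sd_min: 25.0
  meal_amp_median: 35.0
  meal_amp_sigma: 0.55
  meal_rise_min: 45.0
  meal_decay_min: 90.0
  amp_latent_coupling: 0.3
  amp_drift_per_day: -0.015
  noise_sd: 10.5
  noise_rho: 0.8
  biomarker_loading: 0.5
  target_r: 0.4
  biomarkers:
    fbg_mean: 104.0
    fbg_sd: 5.0
    fbg_lo: 100.0
    fbg_hi: 125.0
    fbg_end_shift: -2.8
    fbg_end_noise_sd: 4.0
    hba1c_mean: 6.0
    hba1c_sd: 0.2
    hba1c_lo: 5.7
    hba1c_hi: 6.4
    ogtt_mean: 165.0
    ogtt_sd: 15.0
    ogtt_lo: 140.0
    ogtt_hi: 199.0
    insulin_median: 11.0
    insulin_sigma: 0.35
    hscrp_median: 2.4
    hscrp_sigma: 0.6
    cortisol_mean: 13.0
    cortisol_sd: 3.0
  activity:
    steps_mean: 6800.0
    steps_subject_sd: 1800.0
    steps_day_sd: 1500.0
    steps_z_coupling: -300.0
    hr_mean: 76.0
    hr_subject_sd: 5.5
    hr_day_sd: 2.0
    hr_z_coupling: 1.5
    sleep_mean: 400.0
    sleep_subject_sd: 40.0
    sleep_day_sd: 30.0
    sleep_z_coupling: -5.0
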