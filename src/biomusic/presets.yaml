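# Condition presets: one cell per population x condition.
# Channel means (eda_mean_us, temp_mean_c, ibi_mean_s, breath_interval_s) are
# the reported cohort means for each cell; event rates, amplitudes, jitter and
# noise levels are this package's documented phenomenological defaults
# (see docs/methods.md).
td_anagram_relaxed:
  eda_mean_us: 1.131
  eda_scr_rate_per_min: 4.0
  eda_scr_amp_us: 0.10
  eda_wander_sd_us: 0.02
  temp_mean_c: 32.086
  temp_drift_c_per_min: 0.0
  ibi_mean_s: 0.797
  ibi_jitter_sd_s: 0.05
  breath_interval_s: 3.333
  breath_jitter_sd_s: 0.30
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
td_anagram_anxious:
  eda_mean_us: 3.550
  eda_scr_rate_per_min: 10.0
  eda_scr_amp_us: 0.30
  eda_wander_sd_us: 0.04
  temp_mean_c: 30.412
  temp_drift_c_per_min: -0.05
  ibi_mean_s: 0.761
  ibi_jitter_sd_s: 0.03
  breath_interval_s: 2.269
  breath_jitter_sd_s: 0.15
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
td_stroop_relaxed:
  eda_mean_us: 4.545
  eda_scr_rate_per_min: 4.0
  eda_scr_amp_us: 0.10
  eda_wander_sd_us: 0.02
  temp_mean_c: 30.208
  temp_drift_c_per_min: 0.0
  ibi_mean_s: 0.757
  ibi_jitter_sd_s: 0.05
  breath_interval_s: 2.987
  breath_jitter_sd_s: 0.30
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
td_stroop_anxious:
  eda_mean_us: 8.976
  eda_scr_rate_per_min: 10.0
  eda_scr_amp_us: 0.30
  eda_wander_sd_us: 0.04
  temp_mean_c: 29.467
  temp_drift_c_per_min: -0.05
  ibi_mean_s: 0.706
  ibi_jitter_sd_s: 0.03
  breath_interval_s: 1.546
  breath_jitter_sd_s: 0.12
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
asd_relaxed:
  eda_mean_us: 4.822
  eda_scr_rate_per_min: 4.0
  eda_scr_amp_us: 0.10
  eda_wander_sd_us: 0.02
  temp_mean_c: 28.424
  temp_drift_c_per_min: 0.0
  ibi_mean_s: 0.744
  ibi_jitter_sd_s: 0.05
  breath_interval_s: 2.211
  breath_jitter_sd_s: 0.25
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
asd_anxious:
  eda_mean_us: 7.028
  eda_scr_rate_per_min: 10.0
  eda_scr_amp_us: 0.30
  eda_wander_sd_us: 0.04
  temp_mean_c: 29.251
  temp_drift_c_per_min: 0.0
  ibi_mean_s: 0.686
  ibi_jitter_sd_s: 0.03
  breath_interval_s: 1.616
  breath_jitter_sd_s: 0.12
  noise_sd:
    eda: 0.01
    temp: 0.02
    bvp: 0.02
    resp: 0.01
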