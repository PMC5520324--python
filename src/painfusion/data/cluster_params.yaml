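# painfusion synthetic-cohort parameters, version 1.
#
# Six painful-diabetic-peripheral-neuropathy patient profiles. Binary rates
# (percent) and within-cluster SDs follow the published cluster descriptions;
# continuous means are additionally spread apart across clusters (keeping the
# published ordering: cluster 1 leanest/youngest, cluster 3 oldest, cluster 2
# longest disease duration, cluster 6 most severe pain and sleep interference)
# so that the six components are mutually separable by Ward's minimum-variance
# clustering. See docs/methods.md for the rationale.
#
# feeling frequencies are over the six-point always-to-never scale,
# coded 1=always ... 6=never.
version: 1
cluster_mix: [343, 306, 245, 195, 237, 202]   # normalised internally
aux:
  sleep_slope: 0.9        # sleep(t) tracks pain(t) with this slope
  sleep_noise_sd: 0.6     # residual sleep noise, 0-10 scale units
  feeling_stay_prob: 0.6  # weekly probability a feeling item stays put
clusters:
  1:
    female_pct: 0.0
    age: {mean: 52.3, sd: 8.1}
    bmi: {mean: 24.0, sd: 3.4}
    pdpn_duration: {mean: 10.5, sd: 8.0}
    baseline_pain: {mean: 6.3, sd: 1.3}
    baseline_sleep: {mean: 5.4, sd: 2.2}
    depression_pct: 0.0
    monotherapy_pct: 100.0
    prior_gabapentin_pct: 0.0
    insulin_pct: 3.2
    noise_sd: 0.54
    dose_pct: {75: 9.0, 150: 79.6, 300: 5.5, 600: 0.3, other: 5.6}
    feelings:
      energy: [1.2, 8.1, 11.1, 32.8, 40.1, 6.7]
      calm: [2.4, 13.6, 18.1, 31.9, 32.5, 1.5]
      discouraged: [1.2, 15.1, 27.1, 32.5, 18.1, 6.0]
  2:
    female_pct: 30.1
    age: {mean: 61.0, sd: 7.7}
    bmi: {mean: 30.5, sd: 4.4}
    pdpn_duration: {mean: 24.5, sd: 8.0}
    baseline_pain: {mean: 7.9, sd: 1.4}
    baseline_sleep: {mean: 7.9, sd: 2.2}
    depression_pct: 0.0
    monotherapy_pct: 59.5
    prior_gabapentin_pct: 0.0
    insulin_pct: 100.0
    noise_sd: 0.55
    dose_pct: {75: 14.1, 150: 74.8, 300: 5.6, 600: 1.3, other: 4.2}
    feelings:
      energy: [0.7, 7.9, 6.5, 30.5, 40.5, 13.9]
      calm: [2.5, 15.1, 14.7, 30.8, 30.5, 6.4]
      discouraged: [2.5, 14.7, 29.0, 29.1, 16.9, 7.8]
  3:
    female_pct: 29.8
    age: {mean: 75.8, sd: 7.4}
    bmi: {mean: 32.6, sd: 4.3}
    pdpn_duration: {mean: 12.0, sd: 8.0}
    baseline_pain: {mean: 5.2, sd: 1.4}
    baseline_sleep: {mean: 3.5, sd: 2.4}
    depression_pct: 0.0
    monotherapy_pct: 0.0
    prior_gabapentin_pct: 0.0
    insulin_pct: 18.0
    noise_sd: 0.55
    dose_pct: {75: 15.5, 150: 65.3, 300: 12.2, 600: 2.9, other: 4.1}
    feelings:
      energy: [1.5, 5.0, 11.0, 19.9, 56.7, 5.9]
      calm: [2.0, 16.4, 13.9, 27.4, 37.8, 2.5]
      discouraged: [3.0, 13.4, 33.3, 29.9, 16.4, 4.0]
  4:
    female_pct: 98.5
    age: {mean: 61.2, sd: 7.6}
    bmi: {mean: 35.4, sd: 4.8}
    pdpn_duration: {mean: 2.5, sd: 2.0}
    baseline_pain: {mean: 7.4, sd: 1.5}
    baseline_sleep: {mean: 7.0, sd: 2.3}
    depression_pct: 0.0
    monotherapy_pct: 100.0
    prior_gabapentin_pct: 0.0
    insulin_pct: 16.9
    noise_sd: 0.53
    dose_pct: {75: 10.8, 150: 72.8, 300: 9.7, 600: 3.6, other: 3.1}
    feelings:
      energy: [0.6, 3.7, 11.7, 28.4, 44.4, 11.2]
      calm: [0.0, 14.2, 17.3, 26.5, 35.8, 6.2]
      discouraged: [3.1, 16.1, 26.5, 23.5, 25.9, 4.9]
  5:
    female_pct: 31.7
    age: {mean: 60.5, sd: 9.0}
    bmi: {mean: 30.9, sd: 5.0}
    pdpn_duration: {mean: 6.5, sd: 5.0}
    baseline_pain: {mean: 6.5, sd: 1.3}
    baseline_sleep: {mean: 5.7, sd: 2.1}
    depression_pct: 18.1
    monotherapy_pct: 58.1
    prior_gabapentin_pct: 100.0
    insulin_pct: 78.1
    noise_sd: 0.53
    dose_pct: {75: 16.0, 150: 56.1, 300: 14.8, 600: 11.0, other: 2.1}
    feelings:
      energy: [0.0, 4.8, 8.6, 30.5, 39.1, 17.0]
      calm: [2.9, 12.4, 16.2, 27.6, 32.4, 8.5]
      discouraged: [5.7, 12.4, 26.7, 27.6, 22.9, 4.7]
  6:
    female_pct: 43.1
    age: {mean: 61.2, sd: 8.5}
    bmi: {mean: 34.2, sd: 5.8}
    pdpn_duration: {mean: 12.5, sd: 8.0}
    baseline_pain: {mean: 7.9, sd: 1.3}
    baseline_sleep: {mean: 8.2, sd: 2.2}
    depression_pct: 100.0
    monotherapy_pct: 40.8
    prior_gabapentin_pct: 0.0
    insulin_pct: 57.4
    noise_sd: 0.57
    dose_pct: {75: 13.4, 150: 61.9, 300: 16.8, 600: 3.5, other: 4.4}
    feelings:
      energy: [0.0, 4.8, 8.6, 30.5, 39.1, 17.0]
      calm: [3.2, 4.8, 7.2, 17.6, 50.4, 16.8]
      discouraged: [9.6, 42.4, 28.8, 7.2, 11.2, 0.8]
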