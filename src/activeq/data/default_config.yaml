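# Default study configuration. Every constant the analysis uses that is
# not fixed by the questionnaire itself lives here and can be overridden.
categories:
  # occasions/week midpoint per predefined frequency answer
  frequency:
    "1 time/week": 1.0
    "1-2 times/week": 1.5
    "2-3 times/week": 2.5
    "3-4 times/week": 3.5
    "4-5 times/week": 4.5
    "5-6 times/week": 5.5
    "6 times/week": 6.0
    "7 times/week": 7.0
  # hours-per-occasion midpoint per predefined duration answer
  duration:
    "0.25 h": 0.25
    "0.5 h": 0.5
    "0.75 h": 0.75
    "1 h": 1.0
    "1.25 h": 1.25
    "1.5 h": 1.5
    "1.75 h": 1.75
    "2 h": 2.0
    "2.25 h": 2.25
    "2.5 h": 2.5
    "2.75 h": 2.75
    "3 h": 3.0
    "3.25 h": 3.25
    "3.5 h": 3.5
    "3.75 h": 3.75
    "4 h": 4.0
    "4.25 h": 4.25
    "4.5 h": 4.5
    "4.75 h": 4.75
    "5 h": 5.0
    "5.25 h": 5.25
    "5.5 h": 5.5
    "5.75 h": 5.75
    "6 h": 6.0
    "6.25 h": 6.25
    "6.5 h": 6.5
    "6.75 h": 6.75
    "7 h": 7.0
    "7.25 h": 7.25
    "7.5 h": 7.5
    "7.75 h": 7.75
    "8 h": 8.0
    "8.25 h": 8.25
    "8.5 h": 8.5
    "8.75 h": 8.75
    "9 h": 9.0
    "9.25 h": 9.25
    "9.5 h": 9.5
    "9.75 h": 9.75
    "10 h": 10.0
    "10.25 h": 10.25
    "10.5 h": 10.5
    "10.75 h": 10.75
    "11 h": 11.0
    "11.25 h": 11.25
    "11.5 h": 11.5
    "11.75 h": 11.75
    "12 h": 12.0
scoring:
  sleep_hours: 8.0
  sleep_met: 0.9      # compendium sleeping value; set to 1.0 for the BMR-equivalent variant
  filler_met: 2.0     # MET assumed for under-/over-reported time
  kcal_to_kj: 4.184
dlw:
  rq: 0.85
  fit_windows: [[1, 3], [8, 10]]   # post-dose day ranges used in the log-linear fits
  method: multipoint               # or 'twopoint' (window means, first/last)
  frac_o: 1.007        # 18O fractionation adjustment on the rate-x-space flux
  frac_h: 1.041        # 2H fractionation adjustment
  co2_divisor: 2.078   # mol water flux per mol CO2
  frac_loss: 0.0246    # fractionated water-loss correction coefficient
  frac_loss_scale: 1.05
  weir_o2: 3.941       # kcal per litre O2
  weir_co2: 1.106      # kcal per litre CO2
  litres_per_mol: 22.4
  dose_2h_atoms_per_g: 0.004209   # mol excess 2H per g bulk dose
  dose_18o_atoms_per_g: 0.005156  # mol excess 18O per g bulk dose
agreement:
  icc_model: oneway    # or 'twoway'
  loa_sd_factor: 2.0   # limits of agreement at +/- 2 SD of the differences
cohort:
  n: 37
  seed: 0
  female_fraction: 0.81
  age_band_weights: {"20-29": 22, "30-39": 5, "40-49": 5, "50-59": 4, "60-65": 1}
  bmi_mean: 23.0
  bmi_sd: 3.8
  true_tee_mean_kj: 11229.0
  true_tee_sd_kj: 2256.0
  questionnaire_bias_kj: 440.0
  questionnaire_noise_sd: 0.33   # SD of the log-scale reporting error
  retest_reliability: 0.75       # correlation of reporting error across administrations
  enrichment_noise_sd: 0.005     # multiplicative (log-scale) noise on urine enrichments
  domain_shares: {occupation: 2971, transportation: 434, leisure: 2243, sport: 1360}
  clamp_to_feasible: true
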