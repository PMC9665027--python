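# Recreation of the natalizumab phase III trial design: 2:1 randomization
# (n = 80 on 300 mg q4w for 104 weeks vs n = 40 untreated), patients included
# only with >= 1 relapse in the year before screening and none in the final
# month; KM follow-up axis to 116 weeks with the primary milestone at 104.
seed: 7
population:
  lesion_load: {HIGH: 1.0}
  oligoclonal_bands: {PRESENT: 1.0}
  onset_age: {18-29: 0.494, 30-39: 0.362, 40-49: 0.144}
  disease_duration_years: 5
inclusion:
  min_relapses_lookback: 1
  lookback_window_days: 365
  exclusion_window_days: 30
  require_symptomatic: true
arms:
  - {name: natalizumab, target_n: 80, drug: NATALIZUMAB, dose_mg: 300,
     interval_days: 28, start_week: 0, end_week: 104}
  - {name: control, target_n: 40, drug: NONE}
allocation_ratio: [2, 1]
runin_years: 5
trial_weeks: 116
milestones: [104]
expected_inclusion_rate: 0.18
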