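# Population 1: later disease onset (30-39 / 40-49), high lesion load.
# 5-year treatment-naive histories; symptomatic selection only.
seed: 1
population:
  lesion_load: {HIGH: 1.0}
  oligoclonal_bands: {PRESENT: 0.9, ABSENT: 0.1}
  onset_age: {30-39: 0.5, 40-49: 0.5}
  disease_duration_years: 5
  n_candidates: 345        # ~200 expected symptomatic at the documented 58%
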