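# Population 2: youngest onset category (18-29), low/medium lesion load.
seed: 2
population:
  lesion_load: {LOW_MEDIUM: 1.0}
  oligoclonal_bands: {PRESENT: 0.9, ABSENT: 0.1}
  onset_age: {18-29: 1.0}
  disease_duration_years: 5
  n_candidates: 340        # ~200 expected symptomatic at the documented 59%
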