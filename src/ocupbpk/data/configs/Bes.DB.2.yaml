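# Study Bes.DB.2: single 50 µL drop of besifloxacin 0.6% suspension (DB_rabbit),
# modeled as mixed ophthalmic solution + controlled release.
mode: simulate
seed: 0
study_code: Bes.DB.2
drug:
  builtin: besifloxacin
formulation:
  preset: besivance_mixed_cr
physiology:
  species: DB_rabbit
protocol:
  doses:
    - {time: 0 h, volume: 50 uL}
  t_end: 24 h
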