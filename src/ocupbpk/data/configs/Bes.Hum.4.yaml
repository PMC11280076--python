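# Study Bes.Hum.4: four 50 µL drops of besifloxacin 0.6% ten minutes apart
# (human), modeled as mixed ophthalmic solution + controlled release.
mode: simulate
seed: 0
study_code: Bes.Hum.4
drug:
  builtin: besifloxacin
formulation:
  preset: besivance_mixed_cr
physiology:
  species: human
protocol:
  doses:
    - {time: 0 min, volume: 50 uL}
    - {time: 10 min, volume: 50 uL}
    - {time: 20 min, volume: 50 uL}
    - {time: 30 min, volume: 50 uL}
  t_end: 24 h
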