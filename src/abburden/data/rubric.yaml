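# Default ABB rubric configuration (mirrors ABBCutoffs).
# Lengths in cm; the ptosis criterion is strict equality with the grade.
rubric:
  sn_n_min: 26.0
  n_imf_min: 14.0
  bw_min: 16.0
  ptosis_qualifying_grade: 3.0
  symptom_points: 1
  finding_points: 1
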