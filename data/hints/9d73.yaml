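# B1.23.2 mAb Fab / HLA-B*44:05 cryo-EM complex. SYNTHETIC best-effort
# hints (see README.md). Antibody variable-domain ranges: V_H residues
# 1-113, V_L residues 1-107.
roles:
  A: mhc_heavy
  B: beta2m
  C: peptide
  H: ab_heavy
  L: ab_light
segments:
  ab_heavy/VH: [1, 113]
  ab_light/VL: [1, 107]
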