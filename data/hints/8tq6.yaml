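# Fab / HLA-B*44:05 crystal (two copies in the asymmetric unit; these hints
# select ONE copy by naming only its chains). SYNTHETIC best-effort hints
# (see README.md): verify chain ids against the downloaded file.
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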