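# KIR3DL1 / HLA-B*57:01 complex. SYNTHETIC best-effort hints (see
# README.md): verify chain ids against the downloaded file. D0/D1/D2 ranges
# are approximate Ig-domain boundaries for the three-domain receptor.
roles:
  A: mhc_heavy
  B: beta2m
  C: peptide
  D: receptor
segments:
  receptor/D0: [1, 98]
  receptor/D1: [99, 199]
  receptor/D2: [200, 310]
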