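# KIR2DL2 / HLA-C complex. SYNTHETIC best-effort hints (see README.md):
# verify chain ids against the downloaded file. D1/D2 ranges are approximate
# Ig-domain boundaries for KIR2DL2 (two-domain receptor).
roles:
  A: mhc_heavy
  B: beta2m
  C: peptide
  D: receptor
segments:
  receptor/D1: [1, 101]
  receptor/D2: [102, 210]
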