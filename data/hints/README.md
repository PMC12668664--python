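# Chain-role hints for the deposited comparison structures

These YAML files map chain identifiers to semantic roles (and name domain
segments) for the deposited complexes used by the accession-based regression
checks. They are SYNTHETIC best-effort assignments written without access to
the deposited files: chain ids follow the usual MHC-I deposition convention
(A = heavy chain, B = β2-microglobulin, C = peptide, D = receptor) and the
KIR D1/D2 and antibody V_H/V_L segment ranges are approximate domain
boundaries. Verify chain ids against the actual files after downloading
(`python scripts/fetch_structures.py`) and edit as needed — the regression
test reads whatever these files say.
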