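reference_fasta: synthetic_znsite_reference.faa
triad_columns:
- 120
- 180
- 220
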