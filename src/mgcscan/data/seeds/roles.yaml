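roles:
  CorrinoidProtein: synthetic_corrinoidprotein.faa
  GlyReductase: synthetic_glyreductase.faa
  H4folateMethylase: synthetic_h4folatemethylase.faa
  MarHDK: synthetic_marhdk.faa
  Mlp: synthetic_mlp.faa
  RamRACE: synthetic_ramrace.faa
  SelA: synthetic_sela.faa
  SelB: synthetic_selb.faa
  SelD: synthetic_seld.faa
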