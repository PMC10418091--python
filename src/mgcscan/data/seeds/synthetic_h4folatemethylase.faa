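>seed_h4folate synthetic seed protein, role H4folateMethylase
QDHMPYALLPNQRRHLWHSKSYNNDTCMQFAQRRNTVRAHLCPMNRMMNDDWRKMLMHDR
ASTMHNNYWPHWHSEPYTHHPEWDYNWEQALFKCPVLINSPFACNQQVWTYIMITDVENR
DTTMRCCSPWKWTRELPADNLVMIFVTVTHDSTIPAMQLQANSQRPQGHNIFKEDAASLR
YRTRIRMTVKHYYVQYKSGHFCQHFPKTGKSDFCCGVMYGANVRWGSACWAFEVSNYRGT
EAHSIHMSESIRIYSFAQYDMCKTWHIEIFWILWDILEPAVCQDQQYNYDYGMHGTDQAF
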