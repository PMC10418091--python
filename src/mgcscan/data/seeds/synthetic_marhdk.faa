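>seed_marHDK synthetic seed protein, role MarHDK
GSCCRWWAWVHCMDEGDGLIYSDDMKKLRDVIGENYDWLHHTRMMNQMGMNKVYDQSCPT
MVASGHGPGGTHVSAFIHPYDDKRVQSSVCDRRWIMSTQHAPRNDGGEVSTECQEDKNNS
TIENVHMSFDANNCDNTHDFLMKIVYMCEITWTIGLEFERKVNETAPKSPTPKVQINTME
NHQVILYRGQHCPFKLQIVVRNRPSEENKDQDSSNSFESIISSPYNHEHCCCNKTTCWLM
NNDCISPWGDAYNCHFWTEFQPVCWWMAIYKCDHTQSNET
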