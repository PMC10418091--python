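>seed_ram synthetic seed protein, role RamRACE
EHSYHAWQAWRPEQFIAFRDTDENRMWSCLTEPGSNRAEFDLSTKESGFFCLFKCHRRDM
GDLRFHRAQQWMPYRITSETYSYYTHFGIYKKNSGQIDLHWTLFHEYIFMKLARWEYHVA
HIPIVIKTLIMQCIITADLGDSMPCPERFHYITFRWHNTVFMENCKPWMDCRGNMVRCTK
MPQMWDNIKRPNSGLCMFFFNRHFSTDIDCFSVNMDILCWAMDRKMKGEPLWHTSAFCCT
QQVAFTAASVRTDYMNARHSPWIRTSPIAYCILKICRCPKEFKGNCTYHHSDKQFMEIAV
AWNGEWSHCEDVVNCWFLGIKAYYPLPYSPVYKMCDKAKDCQINCIDECFHDLSRHLPIP
AAGIACFGGLHWMMMYSPCHTTMFVEGSGDVAASLWHFVK
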