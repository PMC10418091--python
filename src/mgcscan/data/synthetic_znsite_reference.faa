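>seed_mlp2 synthetic Mlp2 seed; curator-annotated Zn-triad example
HYEMPWQKPCMRCCSQIKMFWHCMSPMMPREYWKFCIPPRAEETEYSHADLWVQCQISGA
CNKAKDHIWVFVWRGNPEGAFLWVLTKDFSGASIGMWSMDLENFMEEDTNEEEGYNFDRH
SVCIYCWMSKTLVSTTSWVPGWDRMYIKFYHAQKWQCSLFREWIIWMCDFWYMFLFMSEC
VATTMFCVAFNHIEAQIMAPEYDCPCQKWKQCFHMQTGTCKYICRWVRYLFKDDLQGTRC
GYQADYQGCHFMPPSRNAQWHLPTRPAGELNSKWMGFTQWFLTQCFCDGNHFWMKRGAKM
CVYCKCYMWTETEQIASTVTAPWCNDTYLR
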