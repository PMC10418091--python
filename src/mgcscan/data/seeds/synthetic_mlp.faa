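>seed_mlp1 synthetic seed protein, role Mlp
IGRRTQGMYVQTEQMYFHTYLWPPRTTFSNSCKFCNCKENDWCPQHICWSIMPNARNQRA
RNRFMDDWWANNFQCPNPHRGTEYWDFPPIQRCTHGEIHVSTLAINGHFALIQMKAIMVH
ATCQPEGTNYFINNIWGRAQMIAFRYVNMWDQTEHTQFTPEPNRTNGENYCKQQICWMVC
TDMVIARFWVYEGKPGCDRDNDTDIVLPCWERKEDQNQLCVIMEHLVRVIWVQHNPMAVD
TNKMYYCKVAAWHSIYPCGWTPRFPCSSDWRAKEPLFHLEEEASNYYGCYSSQPQKFIRE
SEMKNFYEAAHQCPSERHLNMIDEYTFSRF
>seed_mlp2 synthetic seed protein, role Mlp
HYEMPWQKPCMRCCSQIKMFWHCMSPMMPREYWKFCIPPRAEETEYSHADLWVQCQISGA
CNKAKDHIWVFVWRGNPEGAFLWVLTKDFSGASIGMWSMDLENFMEEDTNEEEGYNFDRH
SVCIYCWMSKTLVSTTSWVPGWDRMYIKFYHAQKWQCSLFREWIIWMCDFWYMFLFMSEC
VATTMFCVAFNHIEAQIMAPEYDCPCQKWKQCFHMQTGTCKYICRWVRYLFKDDLQGTRC
GYQADYQGCHFMPPSRNAQWHLPTRPAGELNSKWMGFTQWFLTQCFCDGNHFWMKRGAKM
CVYCKCYMWTETEQIASTVTAPWCNDTYLR
>seed_mlp3 synthetic seed protein, role Mlp
RWPTIEYQLEPECVWRIMKLPHSFFKQPVTCAEDFVSESHDEVFDGMGAVTCPKKMMSRD
LDQYYCWCCGQQKNPQPLSIAYRAWCHKWSTWIAAWWWMFYFEHAGMYLQIRLDHPQWDH
IMLISLQTHPWNTPSNRKMAHKNPSTNWAVIWYFKLIPTYNHRADLMKLHMNQREHQFSC
LVAKTAHWAVQGNHWFSPHPMWAGFIMGAHSAHRGVEQICSLVADDENHITMSYDTVVLI
NTSKTKYGCIQQQDEKYINDPVPKRMGQLVGCLNEDLFGPFACIGKAMSWDKDPDPKTHP
QRGAYAIEPWPMWLLLNAHLQECWILRSPI
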