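>seed_glyreductase synthetic seed protein, role GlyReductase
LFVGKTQAMKQCVFEGEYDAYLCHDEYLMGCQTCPDGGIKRIFGFIWVANDYQEVISNNT
CNAWYFAPSDMPFTEFIFIYCSRWDGVDPYIQEDVFFAYQYHISRFDPAVKTSGKRDMEY
WDIAAVEEPHMKKLIETWVLHTAAPIRMNRYKTEVQYCCKCCKNGHDRFLDHHFMQHYGC
RQMEKLYMYKENAMFQEDSIDHRKLMQRTLSLAKWDFYIGDNIVVRAGGQYNDKLMSTQK
INNIVEYVRFIWRSLWVLITFESNYWLTQGEAINRIHMVNWTMWLNIGISSDIPRGSYAP
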