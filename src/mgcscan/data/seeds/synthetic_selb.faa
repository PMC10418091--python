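>seed_selB synthetic seed protein, role SelB
GRATEGVYDPLLWMMLESGAMMSCVRSVYAPVCENLKWFLPRSESASYWSYKCPPIRQPG
DNDGYIKNNVNYKDEKFCMEKARFRESSGEWLSQRIKQPVKKNLMTKEDKGTGHTSVLPQ
IQFDQLRVHAEFKCLQSCKFYDRRQKNGAVMVQHYSCFLSLASTLKFDTPELNNMNDWPK
MATSSRERLLYLLRGPIQECECGREDEWISQVNEMHVYEKLHFKYPSYYVGDASSVNCIR
RVIDLCNHFPIMNMTLEHKPHKQCNDWIEEMASEKTGEQGCPSVQAIGPYYPYPYEGLGI
FSWNTRHLHLFKARADNLMCRIQEGGQFEPLTAFYENAYQTQNDQEFGANDSTDARCMKY
MMMGCNRGDFIYKWQELYGISHGDGNDEEQLTQDMTNHLPMAYHAYTDSNDGVCNHTLRL
DGVISTGTVPSMLLQDFWMFTKQMDPKLFF
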