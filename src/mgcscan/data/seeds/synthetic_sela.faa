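>seed_selA synthetic seed protein, role SelA
DNTTAKFCWHPEHPWFHDEPDPISHAGSWRGNWRRRKRQHDLGRNTSWCMAATTGVRRWG
HDNLHDAYRTRMPDTLDKVCGQQEPGKKGYRRTGIQQGHYLGWNLWGCMYHPAAIWMPWA
PRIIIGGIQGNAVFVPDHCWNTPIMFCADRIKPSREQPDPNEHGHSWQRTKLNDNYKHSE
GRICRPEDTSVYTLSVSMSYKTPNMGKEFEQPEGDLVIERDTYAETWFACQQMNSRVKEH
DMKGRKVVSNEPRNLTFKDWHKNQYNGTHLSWWIDYCREIIQCMHGRTIFQDEWTKEIEW
LCQFCNTQILISSIKYRTKIKRKNVPETFDKDSIGCALFLRICVQWRIPC
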