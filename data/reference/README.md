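# Reference protein sequences (user-supplied)

The worked alignment examples compare real proteins; their sequences are
not redistributed here.  To run them, download the following FASTA files
into this directory (one record per file, any description line):

| file                  | protein                                      | source                                   |
|-----------------------|----------------------------------------------|------------------------------------------|
| `CLJU_RS09375.fasta`  | *C. ljungdahlii* Mlp3 (locus CLJU_RS09375)   | NCBI Protein (locus tag CLJU_RS09375)    |
| `O30640.fasta`        | *M. barkeri* MtbA                            | UniProt/Swiss-Prot O30640                |
| `O87604.fasta`        | OdmB phenolic O-demethylase                  | UniProt O87604                           |
| `Q6W001.fasta`        | VdmB phenolic O-demethylase                  | UniProt Q6W001                           |

e.g.

    curl -o O30640.fasta https://rest.uniprot.org/uniprotkb/O30640.fasta

With the first two files present, `tests/test_acceptance.py` verifies the
Smith-Waterman (BLOSUM62, gap 11/1) percent identities against the
published values (32.5% for CLJU_RS09375 vs MtbA; 17.6% vs OdmB when
supplied), and `scripts/acceptance.py` reports them.
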