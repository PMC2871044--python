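>mtDNA-HVRI
ATCGATGTGGGTCGTCAGCTGTATTTCGTACATTACTGCCATTCTGGCAGAACAGCTATC
ATTCCCGGGTAGAGAATCCGGACCGCCGCCAAAGTACACTATAACGTGGGCCTCCATATG
TACCCATGCTTACAAGCAAGCAGACTGGGTACAAGCAAGCACAGCAATCATCAGGCCGCA
CTTCTGTTCGAAACACATGGCGCCTTCAATTCTTAACCTGTGGTCCTATTCTCAAACCTA
CCCACCCTTACCTAGTGCATC
>mtDNA-COI
GCTAAGAGGGCCCCGACTGCCACTTTACTAGGATTATCTGCCCTGTTCCAAGACTCGCTA
ACCTT
>LCT
CTGCGCTGGCAATACAGATAAAAGTCGTCCTGGGTCCATTGGCTCTACAGGCTCCTCCTT
AGGTTGCATTTG
>MCPH1
TTGCAAAGAAATATTGCAGGTCATGCACCCTGGAGTCAATGCAACAATTTCTGCGGTATG
TCTCAGGAGACGTTTG
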