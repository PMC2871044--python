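locus	pcr_id	platform	status	n_ancestral	n_derived
LCT	1	clones	ok	30	0
LCT	2	clones	ok	30	0
LCT	3	clones	no_amplification	0	0
LCT	4	454	ok	45101	19
MCPH1	1	clones	ok	40	0
MCPH1	2	clones	no_amplification	0	0
MCPH1	3	clones	ok	35	0
MCPH1	4	clones	ok	40	0
MCPH1	5	clones	ok	38	0
MCPH1	6	clones	no_amplification	0	0
MCPH1	7	clones	no_amplification	0	0
MCPH1	8	454	ok	12494	189
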