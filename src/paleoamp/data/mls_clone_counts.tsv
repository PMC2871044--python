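locus	fragment	pcr_id	status	n_endogenous	n_contaminant
mtDNA-HVRI	16109-16191	1	ok	20	0
mtDNA-HVRI	16109-16191	2	ok	18	2
mtDNA-HVRI	16109-16191	3	ok	20	0
mtDNA-HVRI	16220-16282	1	ok	17	3
mtDNA-HVRI	16220-16282	2	ok	16	4
mtDNA-HVRI	16220-16282	3	ok	15	5
mtDNA-COI	6267	1	no_amplification	0	0
mtDNA-COI	6267	2	ok	17	3
mtDNA-COI	6267	3	ok	19	1
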