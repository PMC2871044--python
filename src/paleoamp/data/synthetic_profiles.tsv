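person_id	mt_motif	nuclear_genotypes
LL	16126C,16152G,16234C,16258G	LCT:-13910=T/T;MCPH1:37995=C/C
MR	16126C,16152G,16234C	LCT:-13910=T/T;MCPH1:37995=C/C
SV	16152G,16258G	LCT:-13910=T/T;MCPH1:37995=C/C
GC	16126C	LCT:-13910=T/T;MCPH1:37995=C/C
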