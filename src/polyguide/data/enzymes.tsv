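name	recognition_site	cut_offset
BstUI	CGCG	2
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
AluI	AGCT	2
HaeIII	GGCC	2
TaqI	TCGA	1
MspI	CCGG	1
DdeI	CTNAG	1
HinfI	GANTC	1
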