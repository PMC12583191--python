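metabolite_code	parent_code	mw_metabolite	mw_parent	fue	is_edi_eligible	analyte_class
MMP	DMP	180.16	194.18	0.69	1	phthalate
MEP	DEP	194.18	222.24	0.69	1	phthalate
MiBP	DiBP	222.24	278.34	0.69	1	phthalate
MnBP	DnBP	222.24	278.34	0.69	1	phthalate
MBzP	BBzP	256.25	312.36	0.73	1	phthalate
MEHP	DEHP	278.34	390.56	0.062	1	phthalate
MEHHP	DEHP	294.34	390.56	0.149	1	phthalate
MEOHP	DEHP	292.33	390.56	0.109	1	phthalate
MECPP	DEHP	308.33	390.56	0.132	1	phthalate
MCPP	MCPP	252.22	252.22	1.0	0	phthalate
BPA	BPA	228.29	228.29	1.0	1	bisphenol
BPS	BPS	250.27	250.27	1.0	1	bisphenol
BPF	BPF	200.23	200.23	1.0	1	bisphenol
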