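gene	patient	chrom	pos	cytoband	substitution	aa_change	consequence	primary	axillary	metastasis_1	metastasis_2
AKAP3	pat19	chr12	4725047	12p13.32	G>A	Ser807Leu	nonsynonymous	0.02		0.13	0.41|0.22
AKAP4	pat8	chrX	49958130	Xp11.22	A>G	Phe412Leu	nonsynonymous	0.0	0.0	0.22	0.26
AKAP9	pat7	chr7	91630327	7q21.2	A>G	Ile366Val	nonsynonymous	0.04		0.24|0.36
AKAP11	pat12	chr13	42875448	13q14.11	G>A	Asp856Asn	nonsynonymous	0.0		0.08
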