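gene	patient	chrom	pos	cytoband	substitution	aa_change	consequence	primary	metastasis_1
AKAP5	P2	chr14	64935761	14q23	G>A	Asp217Asn	nonsynonymous	0.052	0.0
AKAP6	P1	chr14	33293693	14q12	G>A	Gly2225Glu	nonsynonymous	0.0	0.17
AKAP8	P4	chr19	15484018	19q13.12	G>A	Gln169X	nonsense	0.0	0.15
AKAP9	P1	chr7	91708964	7q21.2	G>A	Ser2518Asn	nonsynonymous	0.0	0.09
AKAP10	P1	chr17	19861659	17p11.2	A>G	Leu182Pro	nonsynonymous	0.0	0.16
AKAP12	P5	chr6	151670403	6q25.1	G>A	Gly293Arg	nonsynonymous	0.0	0.22
AKAP12	P10	chr6	151671474	6q25.1	G>A	Ala650Thr	nonsynonymous	0.0	0.15
AKAP13	P4	chr15	86124141	15q25.3	C>T	Gln948X	nonsense	0.0	0.10
AKAP13	P5	chr15	86122728	15q25.3	G>A	Asp477Asn	nonsynonymous	0.0	0.16
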