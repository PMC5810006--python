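gene	chrom	start	end	cytoband	cohort2_amp	cohort2_del
AKAP1	chr17	64200000	64300000	17q22	10
AKAP5	chr14	64900000	65000000	14q23		2
AKAP6	chr14	33000000	33500000	14q12
AKAP7	chr6	130400000	130600000	6q23.2
AKAP8	chr19	15400000	15500000	19q13.12
AKAP11	chr13	42800000	42900000	13q14.11
AKAP12	chr6	151500000	151700000	6q25.1		3
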