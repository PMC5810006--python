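gene	patient	lesion	call
AKAP1	P4	metastasis	amp
AKAP7	P1	primary	del
AKAP7	P1	metastasis	del
AKAP7	P2	metastasis	del
AKAP7	P5	primary	del
AKAP7	P5	metastasis	del
AKAP8	P4	metastasis	amp
AKAP11	P1	primary	del
AKAP11	P1	metastasis	del
AKAP11	P3	metastasis	del
AKAP11	P8	metastasis	del
AKAP12	P1	primary	del
AKAP12	P1	metastasis	del
AKAP12	P2	metastasis	del
AKAP12	P5	primary	del
AKAP12	P5	metastasis	del
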