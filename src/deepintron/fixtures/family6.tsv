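family	individual	father	mother	sex	phenotype	rs397515893	rs113195070
6	I-2	0	0	1	2	het	het
6	II-1	I-2	0	1	2	het	het
6	II-2	I-2	0	0	1	het	ref
6	II-3	I-2	0	0	1	het	ref
6	II-4	I-2	0	0	1	ref	ref
6	II-5	I-2	0	0	1	ref	ref
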