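family	individual	father	mother	sex	phenotype	rs200411226
15	I-1	0	0	0	2	het
15	II-1	I-1	0	0	2	het
15	III-1	II-1	0	0	2	het
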