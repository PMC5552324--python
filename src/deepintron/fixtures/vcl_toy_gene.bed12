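10	1000	5150	VCL	0	+	1000	5150	0	3	200,200,150	0,2000,4000
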