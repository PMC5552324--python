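10	1500	1650	FOS
10	1480	1700	JUN
10	1450	1600	EP300
10	8000	8200	GATA4
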