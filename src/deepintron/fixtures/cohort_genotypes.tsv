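sample	sex	rs77884406	rs113195070	rs28595759	rs2243452	rs2253324	rs141541040	rs7079796	VCL:c.169-7572C>T	VCL:c.239+4299C>A	rs12570315	LDB3:c.548+1914C>T	rs779483568	rs2040571	rs62478182	rs114394151	rs5956217	rs42887	rs12693162	rs141348126	rs2131959	rs10509614	rs80259697	rs142156368	rs2562845	rs72650063	rs2742353	rs397515893	rs387907267	rs200411226
P01	M	het	het	het	het	het	hom_ref	het	het	het	het	het	het	het	het	het	het	het	het	het	hom_alt	het	het	het	het	hom_ref	het	hom_ref	hom_ref	hom_ref
P02	M	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	het	het	hom_ref	hom_ref	hom_ref	het	het	hom_ref	het	het	hom_ref	hom_alt	hom_ref	hom_ref	het	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P03	M	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	het	het	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P04	M	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	het	het	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P05	M	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	het	het	hom_ref	hom_ref	hom_ref	hom_ref
P06	M	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref
P07	M	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref
P08	M	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref
P09	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P10	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P11	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_alt	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P12	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P13	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P14	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
P15	F	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het
P16	F	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	het	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref	hom_ref
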