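patient	gene	var_id	hgvs	protein	genotype	clinvar	acmg_class
1	TNNT2	rs727504869	c.198G>C	p.Lys76Asn	het	VUS	VUS
2	MYBPC3	rs587776699	c.1224-19G>A	NA	het	conflicting	VUS
5	TTN	rs781121273	c.57478C>G	p.Leu19160Val	het	VUS	VUS
6	MYBPC3	rs397515893	c.1227-13G>A	NA	het	reported_pathogenic	pathogenic
7	TPM1	rs730881151	c.62G>T	p.Arg21Leu	het	conflicting	VUS
8	MYBPC3	rs387907267	c.2827C>T	p.Arg943*	het	reported_pathogenic	pathogenic
12	TPM1	rs397516394	c.841A>G	p.Met281Val	het	VUS	VUS
14	MYH6	rs140596256	c.292G>A	p.Glu98Lys	het	VUS	VUS
14	GLA	GLA:c.187T>A	c.187T>A	p.Cys63Ser	het	novel	VUS
15	MYBPC3	rs200411226	c.1484G>A	p.Arg495Gln	het	reported_pathogenic	likely_pathogenic
16	MYH6	rs140596256	c.292G>A	p.Glu98Lys	het	VUS	VUS
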