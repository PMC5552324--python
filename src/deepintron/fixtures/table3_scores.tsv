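tools	gene	var_id	hgvs	cadd_phred	gwava_region	genomiser	spidex_dpsi	maf_1000g	maf_gnomad	proband_freq
CADD, GWAVA, GENOMISER	VCL	rs77884406	c.169-2410A>C	17.55	0.59	0.910891	NA	0.019	0.0273	0.03125
CADD, GWAVA, GENOMISER	VCL	rs113195070	c.499+367T>C	16.93	0.6	0.963367	NA	0.06	0.0671	0.1875
CADD, GWAVA, GENOMISER	ACTC1	rs28595759	c.129+472T>C	21.9	0.53	0.9792082	NA	0.07	0.0604	0.03125
CADD, GWAVA, GENOMISER	TTN	rs2243452	c.32929+72T>C	22.2	0.53	0.939604	0.6211	0.029	0.0247	0.03125
CADD, GWAVA, GENOMISER	TTN	rs2253324	c.10361-138C>T	18.03	0.51	0.825743	3.3164	0.048	0.0441	0.03125
CADD, GWAVA, GENOMISER	PRKAG2	rs141541040	c.1234-317T>G	15.20	0.58	0.872277	NA	0.003	0.0010	0.03125
CADD, GENOMISER	VCL	rs7079796	c.168+1165C>T	15.74	0.35	0.812872	NA	0.2	0.2191	0.15625
CADD, GENOMISER	VCL	VCL:c.169-7572C>T	c.169-7572C>T	15.88	NA	0.905941	NA	.	.	0.03125
CADD, GENOMISER	VCL	VCL:c.239+4299C>A	c.239+4299C>A	18.78	NA	0.983169	NA	.	0.0001	0.0625
CADD, GENOMISER	LDB3	rs12570315	c.93+1827G>A	16.75	0.23	0.858416	NA	0.3	0.3436	0.25
CADD, GENOMISER	LDB3	LDB3:c.548+1914C>T	c.548+1914C>T	21.4	NA	0.970297	NA	.	.	0.03125
CADD, GENOMISER	LDB3	rs779483568	c.548+1993C>T	17.35	NA	0.990099	NA	.	0.0001	0.03125
CADD, GENOMISER	MYL2	rs2040571	c.3+604C>T	15.58	0.36	0.89703	NA	0.086	0.0888	0.03125
CADD, GENOMISER	PRKAG2	rs62478182	c.467-44847T>G	17.95	0.26	0.880198	NA	0.34	0.3721	0.25
CADD, GENOMISER	PRKAG2	rs114394151	c.115-30242C>T	18.38	0.49	0.925743	NA	.	0	0.0625
CADD, GENOMISER	LAMP2	rs5956217	c.1094-2886A>G	15.93	0.42	0.881188	NA	0.004	0.0009	0.03125
CADD, GENOMISER	LAMP2	rs42887	c.1094-2924C>T	20.4	0.43	0.929703	NA	0.11	0.1711	0.125
CADD, GWAVA	TTN	rs12693162	c.37112-700G>A	18.66	0.5	0.190099	NA	0.22	0.2261	0.21875
CADD, GWAVA	LAMP2	rs141348126	c.1094-140A>G	15.68	0.5	0.545545	NA	.	0	0.03125
GWAVA, GENOMISER	VCL	rs2131959	c.2132-437G>C	10.13	0.57	0.89604	NA	0.75	0.7445	0.84375
GWAVA, GENOMISER	ANKRD1	rs10509614	c.207+239G>T	13.87	0.52	0.838614	0.7561	0.04	0.0314	0.03125
GWAVA, GENOMISER	TTN	rs80259697	c.10360+317T>C	13.04	0.51	0.821782	NA	.	6.68e-05	0.03125
CADD, SPIDEX	TTN	rs142156368	c.31484-286G>T	15.63	0.38	0.425	6.092	0.0089	0.0047	0.0625
SPIDEX	TTN	rs2562845	c.32593+111A>G	3.232	0.29	0	9.1111	0.21	0.2015	0.15625
SPIDEX	TTN	rs72650063	c.32077+31C>G	0.713	0.41	0.019802	5.8489	0.021	0.0218	0.0625
SPIDEX	TTN	rs2742353	c.31484+1715A>C	10.79	0.26	0.556436	6.2975	0.029	0.0247	0.03125
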