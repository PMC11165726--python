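gene_label	p_values	locus	snp_ids	source_ref	hla_flag
MSH5-SAPCD1	5.12E-11	6p21	rs3130484	CR47	0
TNFRSF14/MMEL1	2.10E-08	1p36	rs3748816	CR33	0
GPR35 (2 SNPs)	3.43E-9;2.99E-9	2q37	rs4676410;rs3749171	CR35	0
TCF4	2.61E-08	18q21	rs1452787	CR35	0
MMEL1, TNFRSF14	7.41E-12	1p36	rs3748816	CR36	0
CD28	1.89E-20	2q33	rs7426056	CR35	0
MST1	2.45E-26	3p21	rs3197999	CR36	0
IL2/IL21	8.87E-13	4q27	rs13140464	CR36	0
BACH2	8.36E-12	6q15	rs56258221	CR36	0
IL2RA	8.19E-17	10p15	rs4147359	CR36	0
SIK2	3.17E-09	11q23	rs7937682	CR36	0
HDAC7	5.49E-09	12q13	rs11168249	CR36	0
SH2B3/ATXN2	5.91E-11	12q24	rs3184504	CR36	0
CD226	3.06E-08	18q22	rs1788097	CR36	0
PRKD2/STRN4	6.51E-10	19q13	rs60652743	CR36	0
PSMG1	3.19E-17	21q22	rs2836883	CR36	0
MST1	3.80E-12	3p21	rs3197999	CR38	0
IL2RA (2 SNPs)	1.5E-8;3.4E-7	10p15	rs4147359;rs706778	CR38	0
MST1	1.10E-16	3p21	rs3197999	CR48	0
BCL2L11	4.10E-08	2q13	rs6720394	CR48	0
MMEL1	5.17E-13	1	rs3748816	CR40	0
CD28	2.12E-16	2	rs7426056	CR40	0
MST1	5.11E-26	3	rs3197999	CR40	0
IL2, IL21	1.19E-13	4	rs13140464	CR40	0
BACH2	1.41E-09	6	rs56258221	CR40	0
IL2RA	7.54E-17	10	rs56258221	CR40	0
SIK2	4.77E-07	11	rs7937682	CR40	0
SH2B3	4.27E-13	12	rs3184504	CR40	0
CD226	6.58E-12	18	rs3184504	CR40	0
PRKD2	1.99E-12	19	rs60652743	CR40	0
PSMG1	4.21E-13	21	rs2836883	CR40	0
BCL2L11	2.36E-11	2	rs72837826	CR40	0
FOXP1	2.62E-15	3	rs80060485	CR40	0
CCDC88B	2.24E-13	11	rs663743	CR40	0
CLEC16A	3.59E-13	16	rs725613	CR40	0
UBASH3A	2.19E-12	21	rs1893592	CR40	0
NFKB1	3.81E-10	4	rs17032705	CR41	0
RIC8B	1.29E-09	12	rs12369214	CR41	0
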