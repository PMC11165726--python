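drug_id	name	z	mean	sd	annotations	licensed	medicinal	indication
denileukin_diftitox	Denileukin diftitox	-5.08699	1.992667	0.260665	IL2RB_target_agonist;IL2RG_target_;IL2RA_target_binder	1	1	Cutaneous T-cell lymphoma
basiliximab	Basiliximab	-5.03786	1.9735	0.292485	IL2RA_target_antibody;IL2RB_target_antibody	1	1	Kidney transplant rejection prophylaxis
abatacept	Abatacept	-3.78712	2.4515	0.383272	CD86_target_antagonist;CD80_target_antagonist	1	1	Juvenile idiopathic and rheumatoid arthritis
belatacept	Belatacept	-3.73261	2.4435	0.386727	CD80_target_antagonist;CD86_target_antagonist	1	1	Kidney transplant rejection prophylaxis
girentuximab	Girentuximab	-3.63858	2.317	0.361954	IL2_target_;CA9_target_	0	1	Investigated in gallbladder and renal cell cancer
navitoclax	Navitoclax	-3.51662	1.938333	0.266828	BCL2L2_target_;BAD_target_;BCL2_target_	0	1	Investigated in multiple cancers
isosorbide	Isosorbide	-3.11562	1.790667	0.253775	MCL1_target_;BCL2L1_target_;BCL2_target_	1	1	Angina
tapinarof	Tapinarof	-3.03871	2.185	0.280273	IL2_target_;IL12B_target_;IL6_target_	0	1	Investigated in psoriasis
tg4010	TG4010	-2.9965	1.9765	0.32588	IL2_target_;MUC1_target_	0	1	Investigated in cancers
nfkb_decoy	NF-kappaB Decoy	-2.75936	1.391	0.504102	NFKB1_target_inhibitor	0	1	Investigated in inflammatory disorders
kd3010	KD3010	-2.73881	1.963	0.351612	PPARD_target_	0	1	Investigated in metabolic disease and obesity
cyt997	CYT997	-2.73051	2.00725	0.117103	TUBB1_target_;TUBB2B_target_;TUBA1A_target_;TUBB2A_target_;TUBA1C_target_;TUBA4A_target_;TUBA3E_target_;TUBB6_target_;TUBB4B_target_;TUBA3C_target_;TUBA3C_target_;TUBB3_target_;TUBB4A_target_;TUBA4B_target_;TUBB_target_;TUBA1B_target_	0	1	Investigated in solid tumours
galiximab	Galiximab	-2.71394	2.486	0.547544	CD80_target_antibody	0	1	Investigated in lymphoma, canceers, rheumatoid arthritis
p54	P54	-2.64154	1.448	0.358882	NFKB2_target_;NFKB1_target_	0	1	Investigated in cancers, IBD, OA
spp_301	SPP 301	-2.63165	2.301	0.494367	EDNRA_target_	0	1	Investigated in cardiovascular disorder and diabetic neuropathy
darusentan	Darusentan	-2.57539	2.271	0.493517	EDNRA_target_	1	1	Heart failure, hypertension
actelion_1	Actelion-1	-2.57238	2.28	0.497594	EDNRA_target_	0	1	Investigated in cardiovascular disorder, hypertension, pulmonary hypertension
sgn_30	SGN-30	-2.56224	1.4565	0.373307	NFKB2_target_;NFKB1_target_	0	1	Investigated in autoimmune disease, cancers
nox_700	NOX-700	-2.5602	1.449	0.370674	NFKB2_target_;NFKB1_target_	0	1	Investigated in T2DM
ecallantide	Ecallantide	-2.54378	2.326	0.521272	KLKB1_target_inhibitor	1	1	Hereditary angioedema
atrasentan	Atrasentan	-2.51841	2.259	0.499919	EDNRA_target_	0	1	Investigated in cancers
custirsen	Custirsen	-2.51459	1.436667	0.306213	NFKB2_target_;ESR1_target_;NFKB1_target_	0	1	Investigated in brain/breast cancers
propyl_alcohol	Propyl alcohol	-2.51227	2.095	0.435861	LYZ_target_	1	1	Skin disinfection
clazosentan	Clazosentan	-2.50417	2.272	0.507953	EDNRA_target_	0	1	Investigated in stroke
he3286	HE3286	-2.47432	1.695667	0.281155	NFKB2_target_;CYP3A4_enzyme_substrate;NFKB1_target_	1	1	T2DM and RA
thiocolchicoside	Thiocolchicoside	-2.47009	1.948	0.383792	GLRA1_target_antagonist;TNFSF11_target_antagonist	1	1	Back pain, osteoarthritis, rheumatoid arthritis
lanadelumab	Lanadelumab	-2.46616	2.304	0.528757	KLKB1_target_inhibitor	1	1	Hereditary angioedema, angioedema
fostamatinib	Fostamatinib	-2.41208	2.088189	0.042463		1	1	Chronic immune thrombocytopoenia
cefazolin	Cefazolin	-2.32862	2.392	0.239913	IL15_target_inhibitor;SLC22A8_transporter_inhibitor;ALB_carrier_other/unknown;SLC22A11_transporter_inhibitor;ABCC4_transporter_substrate;PON1_target_inhibitor;IL2_target_inhibitor;SLC22A6_transporter_substrate|inhibitor;TPMT_enzyme_substrate	1	1	Infections
denosumab	Denosumab	-2.32062	1.937	0.403771	TNFSF11_target_antibody	1	1	Osteoporosis
promethazine	Promethazine	-2.28665	2.289389	0.126556	HRH1_target_antagonist;ABCB1_transporter_inhibitor;CHRM2_target_antagonist;P2RY10_target_inhibitor;DRD2_target_antagonist;HRH2_target_antagonist;CHRM1_target_antagonist;SCN9A_target_inhibitor;CYP2D6_enzyme_substrate|inhibitor;CYP2D6_enzyme_substrate|inhibito;ABCC3_transporter_inhibitor;CHRM5_target_antagonist;KCNAB2_target_inducer;ABCC4_transporter_inhibitor;CYP2C9_enzyme_inhibitor;CYP2B6_enzyme_substrate;ALB_carrier_binder;CALM1_target_inhibitor;CALM1_target_inhibitor;CALM1_target_inhibitor;ADRA2C_target_antagonist;CHRM3_target_antagonist;CHRM4_target_antagonist	1	1	Allergy
tezosentan	Tezosentan	-2.25564	2.3155	0.361538	EDNRA_target_;EDNRB_target_	0	1	Investigated in heart failure, liver disease, heart disease
amgn_0007	AMGN-0007	-2.25489	1.95	0.421307	TNFSF11_target_	0	1	Investigated in osteoporosis and bone mets
enrasentan	Enrasentan	-2.16756	2.304	0.370923	EDNRA_target_;EDNRB_target_	0	1	Investigated in heart failure, COPD, BPH
bictegravir	Bictegravir	-2.13883	2.291	0.291904	POU2F2_enzyme_inhibitor;CYP3A4_enzyme_substrate;SLC47A1_enzyme_inhibitor;UGT1A1_enzyme_substrate	1	1	HIV
andrographolide	Andrographolide	-2.11312	1.8174	0.197528	NFKB1_target_;IL6_target_;TNF_target_;NFKB2_target_;IL1B_target_	0	1	Investigated in UC
metronidazole	Metronidazole	-2.10096	2.438	0.208476	ABCB1_transporter_inhibitor;CYP3A4_enzyme_inhibitor;CYP3A5_enzyme_substrate;CYP2A6_enzyme_substrate;CYP3A7_enzyme_substrate;CYP3A7_enzyme_substrate;CYP2C9_enzyme_inhibitor;UGT1A1_enzyme_substrate;CYP2C8_enzyme_inhibitor	1	1	Infections
pseudoephedrine	Pseudoephedrine	-2.03487	1.979214	0.130194	ADRB2_target_partial agonist;MAOA_enzyme_inhibitor;TNF_target_inhibitor;ADRA2A_target_agonist;NFKB1_target_inhibitor;SLC6A4_transporter_inhibitor;SLC6A3_transporter_inhibitor;NFATC1_target_inhibitor;JUN_target_inhibitor;ADRB1_target_agonist|partial agonist;IL2_target_inhibitor;ALB_carrier_binder;ADRA1A_target_agonist;SLC6A2_transporter_inhibitor	1	1	Allergy, congestion
ancestim	Ancestim	-2.02175	1.856	0.423396	KIT_target_agonist	1	1	Stem cell harvest
castor_oil	Castor oil	-2.01682	2.102	0.29849	PTGER4_target_agonist;PTGER3_target_agonist|activator	1	1	Constipation
tucatinib	Tucatinib	-2.01298	2.262714	0.201478	ERBB3_target_inhibitor;SLC22A2_transporter_inhibitor;CYP3A7_enzyme_substrate;CYP3A7_enzyme_substrate;CYP2C8_enzyme_substrate;ABCB1_transporter_substrate;ERBB2_enzyme_inhibitor;SLC47A2_transporter_inhibitor;SLC47A1_transporter_inhibitor;ABCG2_transporter_substrate	1	1	Breast cancer
pazopanib	Pazopanib	-2.01138	2.182278	0.118244	FGFR3_target_inhibitor;FLT4_target_;PDGFRB_target_inhibitor;ITK_target_inhibitor;SH2B3_target_inhibitor;CYP1A2_enzyme_substrate;ABCB1_transporter_substrate;SLCO1B1_transporter_inhibitor;UGT1A1_transporter_inhibitor;KIT_target_inhibitor;CYP2C8_enzyme_substrate|inhibitor;CYP2D6_enzyme_inhibitor;CYP2D6_enzyme_inhibitor;ABCG2_transporter_substrate;KDR_target_inhibitor;CYP3A4_enzyme_substrate|inhibitor;FLT1_target_inhibitor;PDGFRA_target_inhibitor;FGF1_target_inhibitor	1	1	Renal cell, soft tissue, thyroid cancer
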