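name	z_psc	z_pbc	current_use	under_investigation
Denileukin diftitox	-5.087	-3.975	Cutaneous T-cell lymphoma	
Basiliximab	-5.038	-3.320	Kidney transplant rejection prophylaxis	
Abatacept	-3.787	-4.603	RA/psoriatic arthritis/GVHD prophylaxis	
Belatacept	-3.733	-4.709	Kidney transplant rejection prophylaxis	
NF-kappaB Decoy	-2.759	-2.809		inflammatory disorders
CYT997	-2.731	-2.593		solid tumours
Galiximab	-2.714	-4.217		lymphoma, psoriasis, RA
P54	-2.642	-2.362		Cancers, IBD, OA
Arotinoid acid	-2.637	-4.419		psoriasis
SGN-30	-2.562	-2.401		autoimmune disease, cancers
NOX-700	-2.560	-2.461		T2DM
Custirsen	-2.515	-2.206		brain/breast cancers
HE3286	-2.474	-2.163		T2DM and RA
Thiocolchicoside	-2.470	-4.217		rheumatological disorders, muscle contraction
Fostamatinib	-2.412	-3.305	Chronic ITP	
Denosumab	-2.321	-4.416	Osteoporosis	
AMGN-0007	-2.255	-4.203		osteoporosis/bone metastases
Andrographolide	-2.113	-2.592		UC
Tucatinib	-2.013	-2.821	Breast cancer	
Pazopanib	-2.011	-2.462	Renal cell, soft tissue, thyroid cancer	
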