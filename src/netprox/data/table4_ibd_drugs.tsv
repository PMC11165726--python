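name	z
Prednisone	-0.97011
Budesonide	-0.822
Prednisolone	-0.6956
Ozanimod	-0.202
Mesalazine	0.003
Vedolizumab	0.028
Cyclosporine	0.06
Ustekinumab	0.17
Adalimumab	0.27
Golimumab	0.281
Infliximab	0.335
Sulfasalazine	0.686
Tofacitinib	0.851
Tofacitinib	0.851
Mercaptopurine	1.227
Methotrexate	1.369
Azathioprine	1.602
Certolizumab	1.622
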