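name	z	trial_ids	status
Metronidazole	-2.100964165	NCT01085760	n = 18, 77% IBD, split between high and low dose, demonstrated efficacy but didn't meet primary outcome
Volixibat	-0.97191795	NCT04663308	Ongoing
Vancomycin	-0.96744415	NCT03710122;NCT02605213;NCT01802073/NCT01322386;NCT01085760;NCT02137668;NCT03046901;Damman et al. 2018	Recruiting; biochemical improvement in several small trials; insufficient evidence overall
Budesonide	-0.821600362	NCT00004842	Completed - no report
Cladribine	-0.794671207	NCT00004762	Completed - no report
Fenofibrate	-0.644737496	NCT01142323	Terminated - no report
Erlotinib	-0.575691734	NCT00955149	Completed - no report
Docosahexaenoid Acid - DHA, doconexent	-0.467860521	NCT00325013	Completed - no report
Bezafibrate	-0.434430331	NCT04309773;NCT02701166;Mizuno et al. 2015	Studies recruiting/in progress; biochemical improvement
Minocycline	-0.363246802	NCT00630942	Completed - no report
All-trans Retinoic Acid - tretinoin	-0.254372936	NCT03359174;NCT01456468	Terminated - no report
Vedolizumab	0.027695758	NCT03035058	Withdrawn - no report
Xifaxan - rifaximin	0.352010243	NCT01695174	n = 16, 81% IBD, no significant change in biochemistry or symptoms
Sulfasalazine	0.68636947	NCT03561584	Recruiting
Simvastatin	0.880045656	NCT04133792	Recruiting
Ursodeoxycholic acid	1.041833924	NCT01088607;NCT00059202;NCT01456468	Many trials; biochemical improvement, no proven survival benefit
Curcumin	1.108613924	NCT02978339	n = 15, 20% met primary outcome
Obeticholic acid	1.170058504	NCT02177136	n = 76, ALP significantly reduced in 5-10 mg/day
Thalidomide	1.294318063	NCT00953615	Terminated - lack of enrolment
Mitomycin C	1.513646452	NCT01688024	Recruiting
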