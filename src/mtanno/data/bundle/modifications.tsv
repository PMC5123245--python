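position	mod_name	modomics_symbol	trna	evidence
9	1-methyladenosine	""""	Asp	human
9	1-methyladenosine	""""	Leu(CUN)	human
9	1-methyladenosine	""""	Lys	human
9	1-methyladenosine	""""	Pro	human
9	1-methyladenosine	""""	Ala	bovine
9	1-methyladenosine	""""	Glu	bovine
9	1-methyladenosine	""""	Phe	bovine
9	1-methyladenosine	""""	Gly	bovine
9	1-methyladenosine	""""	His	bovine
9	1-methyladenosine	""""	Asn	bovine
9	1-methyladenosine	""""	Arg	bovine
9	1-methyladenosine	""""	Thr	bovine
9	1-methyladenosine	""""	Val	bovine
9	1-methyladenosine	""""	Trp	bovine
9	1-methylguanosine	K	Ile	human
9	1-methylguanosine	K	Leu(UUR)	human
9	1-methylguanosine	K	Cys	bovine
9	1-methylguanosine	K	Gln	bovine
9	1-methylguanosine	K	Tyr	bovine
10	N2-methylguanosine	L	Leu(UUR)	human
10	N2-methylguanosine	L	Leu(CUN)	human
10	N2-methylguanosine	L	Lys	human
10	N2-methylguanosine	L	Asp	human
10	N2-methylguanosine	L	Ala	bovine
10	N2-methylguanosine	L	Phe	bovine
10	N2-methylguanosine	L	Gly	bovine
10	N2-methylguanosine	L	His	bovine
10	N2-methylguanosine	L	Asn	bovine
10	N2-methylguanosine	L	Val	bovine
10	N2-methylguanosine	L	Trp	bovine
10	N2-methylguanosine	L	Tyr	bovine
20	dihydrouridine	D	Leu(UUR)	human
26	N2-methylguanosine	L	Ala	human
26	N2-methylguanosine	L	Glu	human
26	N2,N2-dimethylguanosine	R	Ile	human
27	pseudouridine	P	Asp	human
27	pseudouridine	P	Ile	human
27	pseudouridine	P	Leu(UUR)	human
27	pseudouridine	P	Leu(CUN)	human
27	pseudouridine	P	Lys	human
27	pseudouridine	P	Met	human
27	pseudouridine	P	Pro	human
27	pseudouridine	P	Cys	bovine
27	pseudouridine	P	His	bovine
28	pseudouridine	P	Ile	human
28	pseudouridine	P	Lys	human
28	pseudouridine	P	Leu(CUN)	human
28	pseudouridine	P	Pro	human
28	pseudouridine	P	Cys	bovine
28	pseudouridine	P	Glu	bovine
28	pseudouridine	P	Asn	bovine
28	pseudouridine	P	Ser(UCN)	bovine
28	pseudouridine	P	Tyr	bovine
29	pseudouridine	P	Ser(UCN)	human
31	pseudouridine	P	Leu(CUN)	human
32	3-methylcytidine	'	Ser(UCN)	human
32	3-methylcytidine	'	Thr	human
32	pseudouridine	P	Pro	human
32	pseudouridine	P	Cys	bovine
34	5-taurinomethyluridine	Ê	Leu(UUR)	human
34	5-taurinomethyluridine	Ê	Glu	bovine
34	5-taurinomethyluridine	Ê	Gln	bovine
34	5-taurinomethyluridine	Ê	Trp	bovine
34	queuosine	Q	Asp	human
34	queuosine	Q	His	bovine
34	queuosine	Q	Asn	bovine
34	queuosine	Q	Tyr	bovine
34	5-taurinomethyl-2-thiouridine	Ǝ	Lys	human
34	5-taurinomethyl-2-thiouridine	Ǝ	Glu	bovine
34	5-taurinomethyl-2-thiouridine	Ǝ	Gln	bovine
34	5-formylcytidine	>	Met	human
37	N6-threonylcarbamoyladenosine	6	Ile	human
37	N6-threonylcarbamoyladenosine	6	Lys	human
37	N6-threonylcarbamoyladenosine	6	Ser(AGY)	human
37	N6-threonylcarbamoyladenosine	6	Asn	bovine
37	N6-threonylcarbamoyladenosine	6	Thr	bovine
37	N6-isopentenyladenosine	+	Cys	human
37	N6-isopentenyladenosine	+	Phe	human
37	N6-isopentenyladenosine	+	Ser(UCN)	human
37	N6-isopentenyladenosine	+	Trp	human
37	N6-isopentenyladenosine	+	Tyr	human
37	2-methylthio-N6-isopentenyladenosine	*	Phe	human
37	2-methylthio-N6-isopentenyladenosine	*	Ser(UCN)	human
37	2-methylthio-N6-isopentenyladenosine	*	Trp	human
37	2-methylthio-N6-isopentenyladenosine	*	Tyr	human
37	1-methylguanosine	K	Leu(CUN)	human
37	1-methylguanosine	K	Pro	human
37	1-methylguanosine	K	Gln	bovine
38	pseudouridine	P	Pro	human
39	pseudouridine	P	Ala	human
39	pseudouridine	P	Cys	human
39	pseudouridine	P	Phe	human
39	pseudouridine	P	Gly	human
39	pseudouridine	P	His	human
39	pseudouridine	P	Gln	human
39	pseudouridine	P	Arg	human
39	pseudouridine	P	Tyr	human
40	pseudouridine	P	Glu	human
40	pseudouridine	P	Gln	human
48	5-methylcytidine	?	Leu(UUR)	human
49	5-methylcytidine	?	Glu	human
50	pseudouridine	P	Met	human
54	5-methyluridine	T	Leu(UUR)	human
54	5-methyluridine	T	Pro	human
55	pseudouridine	P	Leu(UUR)	human
55	pseudouridine	P	Pro	human
55	pseudouridine	P	Glu	bovine
55	pseudouridine	P	Gln	bovine
55	pseudouridine	P	Ser(UCN)	bovine
55	pseudouridine	P	Tyr	bovine
58	1-methyladenosine	""""	Ser(AGY)	human
58	1-methyladenosine	""""	Leu(UUR)	human
58	1-methyladenosine	""""	Cys	bovine
58	1-methyladenosine	""""	Ser(UCN)	bovine
58	1-methyladenosine	""""	Glu	model_organism
72	5-methylcytidine	?	Thr	human
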