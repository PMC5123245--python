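position	ref	alt	rsrs	mhcs	rcrs	nt_variability	mitomap_diseases	mitomap_homoplasmy	mitomap_heteroplasmy	clinvar	omim	dbsnp	mamit_trna	phastcons20way	phylop20way
1555	A	G			Yes		Deafness	Y	Y						
4450	G	A	Yes	Yes	Yes	0.00E+00	Myopathy	N	Y				http://mamit-trna.u-strasbg.fr/mutations.asp?idAA=19	0.889764	0.797921
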