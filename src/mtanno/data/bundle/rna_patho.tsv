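position	ref	alt	scheme	raw_score	prediction_label	source_citation
620	A	G	tRNA	6	Neutral	synthetic-fixture
622	C	A	tRNA	7	Possibly pathogenic	synthetic-fixture
900	G	A	rRNA	3	Likely pathogenic	synthetic-fixture
902	T	G	rRNA	2	Not enough evidence	synthetic-fixture
1555	A	G	rRNA	5	Proven pathogenic	literature-curated
4450	G	A	tRNA	13	Possibly/definitely pathogenic	literature-curated
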