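contig	pos_1based	ref	alt	maf_kg1000	maf_evs	maf_exac	dbsnp_common	effect
DNMT3A	131	A	G	0.12	0.10	0.11	1	MODIFIER
DNMT3A	150	C	T	0.0	0.0	0.0	0	HIGH
TET2	140	G	A	0.06	0.0	0.0	0	MODERATE
TET2	155	T	C	0.0	0.0	0.004	0	MODERATE
ASXL1	135	C	A	0.0	0.02	0.0	1	LOW
TP53	145	G	T	0.0	0.0	0.0	0	HIGH
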