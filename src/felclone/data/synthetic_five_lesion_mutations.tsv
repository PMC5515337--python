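# Synthetic stand-in for the five-lesion case: mutation identities and the
# lesion topology follow the published case report; read counts are
# constructed at realistic targeted-panel depths (per-locus figure counts
# are not machine-readable). Coordinates are hg19-approximate.
lesion_id	gene	protein_change	cdna_change	chrom	pos	ref_allele	alt_allele	alt_count	depth	is_promoter
FA1	MED12	Gly44Cys	c.130G>T	chrX	70339328	G	T	312	1040	0
FA2	MED12	Gly44Val	c.131G>T	chrX	70339329	G	T	165	1200	0
FA2	FGFR2	Ser252Trp	c.755C>G	chr10	123279677	G	C	275	1000	0
FA2	KDM6A	Val1207Gly	c.3620T>G	chrX	44969287	T	G	286	1040	0
FA2	KMT2D	Gln4347fs	c.13039del	chr12	49425114	CT	C	220	800	0
FA3	MED12	Gly44Asp	c.131G>A	chrX	70339329	G	A	390	1200	0
FA3	CCND2	Lys154Arg	c.461A>G	chr12	4399000	A	G	125	1100	0
BenignPT	MED12	Gly44Val	c.131G>T	chrX	70339329	G	T	250	1000	0
MalignantPT	MED12	Gly44Asp	c.131G>A	chrX	70339329	G	A	420	1200	0
MalignantPT	TERT	-124C>T	c.-124C>T	chr5	1295228	G	A	350	1000	1
MalignantPT	SETD2	Arg1572His	c.4715G>A	chr3	47125000	C	T	385	1100	0
MalignantPT	SETD2	Phe676fs	c.2028del	chr3	47155000	TC	T	105	1000	0
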