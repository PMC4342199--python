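gene	rsid	drug	chrom	pos	ref	alt	allele_tag
C11orf65	rs11212617	metformin	chrP1	1000	A	C	rs11212617
CYP2C19	rs12248560	clopidogrel	chrP1	2000	C	T	*17
CYP2C19	rs4244285	clopidogrel	chrP1	3000	G	A	*2
CYP2C19	rs4986893	clopidogrel	chrP1	4000	G	A	*3
CYP2C19	rs28399504	clopidogrel	chrP1	5000	A	G	*4
CYP2C19	rs41291556	clopidogrel	chrP1	6000	T	C	*8
CYP2C19	rs72552267	clopidogrel	chrP1	7000	G	A	*6
CYP2C19	rs72558186	clopidogrel	chrP1	8000	T	A	*7
CYP2C19	rs56337013	clopidogrel	chrP1	9000	C	T	*5
CYP2C9	rs1799853	warfarin	chrP1	10000	C	T	*2
CYP2C9	rs1057910	warfarin	chrP1	11000	A	C	*3
CYP2C9	rs7900194	warfarin	chrP1	12000	G	A	*8
CYP2C9	rs9332131	warfarin	chrP1	13000	TA	T	*6
CYP2C9	rs28371685	warfarin	chrP1	14000	C	T	*11
CYP2C9	rs28371686	warfarin	chrP1	15000	C	G	*5
VKORC1	rs9923231	warfarin	chrP1	16000	G	A	-1639G>A
SLCO1B1	rs4149056	simvastatin	chrP1	17000	T	C	*5
ABCB1	rs1045642	digoxin	chrP1	18000	A	G	3435C>T
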