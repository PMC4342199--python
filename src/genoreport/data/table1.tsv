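gene	c_hgvs	p_hgvs	disease	classification	inheritance	section	filters
SPATA7	c.94+2T>C	p.?	Leber congenital amaurosis	LP	AR	Carrier Risk	LOF
ERCC5	c.3238C>T	p.Arg1080X	Xeroderma pigmentosum	LP	AR	Carrier Risk	LOF
COL7A1	c.7557+1G>T	p.?	Epidermolysis bullosa dystrophica	LP	AR	Carrier Risk	LOF
C2	c.841_849+19del	p.Val281_Arg283del	C2 deficiency	LP	AR	Carrier Risk	LOF
MYO7A	c.5648G>A	p.Arg1883Gln	Usher syndrome type I	LP	AR	Carrier Risk	HGMD
NAGA	c.479C>G	p.Ser160Cys	Alpha-N-acetylgalactosaminidase deficiency	LP	AR	Carrier Risk	HGMD
KCNQ1	c.826delT	p.Ser276ProfsX13	Jervell and Lange-Nielsen syndrome	LP	AR	Carrier Risk	LOF
LAMA2	c.5563-2A>G	p.?	Congenital muscular dystrophy type IA	LP	AR	Carrier Risk	LOF
SP110	c.877A>T	p.Lys293X	Hepatic veno-occlusive disease with immunodeficiency	LP	AR	Carrier Risk	LOF
ARSB	c.1450A>G	p.Arg484Gly	Mucopolysaccharidosis type VI	LP	AR	Carrier Risk	HGMD
BEST1	c.602T>C	p.Ile201Thr	Autosomal recessive bestrophinopathy	LP	AR	Carrier Risk	HGMD
ACOX1	c.1851delT	p.Gly618AlafsX24	Peroxisomal acyl-CoA oxidase deficiency	LP	AR	Carrier Risk	LOF
LIFR	c.2074C>T	p.Arg692X	Stuve-Wiedemann syndrome	LP	AR	Carrier Risk	LOF
PAH	c.842+5G>A	p.?	Phenylketonuria	LP	AR	Carrier Risk	HGMD,LOF
MMACHC	c.271dupA	p.Arg91LysfsX14	Methylmalonic aciduria and homocystinuria cblC type	P	AR	Carrier Risk	LOF
CFTR	c.3846G>A	p.Trp1282X	Cystic fibrosis	P	AR	Carrier Risk	HGMD,LOF
PFKM	c.237+1G>A	p.?	Glycogen storage disease 7	P	AR	Carrier Risk	HGMD,LOF
CUBN	c.6928_6934del	p.Glu2310CysfsX3	Imerslund-Grasbeck syndrome	P	AR	Carrier Risk	LOF
DUOX2	c.3847+2T>C	p.?	Hypothyroidism	P	AR	Carrier Risk	LOF
ABCA4	c.5882G>A	p.Gly1961Glu	Stargardt disease	P	AR	Carrier Risk	HGMD
MPO	c.2031-2A>C	p.?	Myeloperoxidase deficiency	P	AR	Carrier Risk	HGMD
SERPINA1	c.1096G>A	p.Glu366Lys	Chronic obstructive pulmonary disease	P	AR	Carrier Risk	HGMD
USH2A	c.1214del	p.Asn405IlefsX3	Usher syndrome type II	P	AR	Carrier Risk	LOF
CLRN1	c.528T>G	p.Tyr176X	Usher syndrome type III	P	AR	Carrier Risk	HGMD,LOF
CYP1B1	c.171G>A	p.Trp57X	Primary congenital glaucoma	P	AR	Carrier Risk	LOF
NLRP7	c.337_338insG	p.Glu113GlyfsX7	Recurrent hydatidiform mole	P	AR	Carrier Risk	LOF
BTD	c.1330G>C	p.Asp444His	Biotinidase deficiency	P	AR	Carrier Risk	HGMD
SPG7	c.1529C>T	p.Ala510Val	Spastic paraplegia type 7	P	AR	Carrier Risk	HGMD
PYGL	c.25_44dup	p.Ser15ArgfsX21	Glycogen storage disease 6	P	AR	Carrier Risk	LOF
WFS1	c.124C>T	p.Arg42X	Wolfram syndrome	P	AR	Carrier Risk	LOF
CYP1B1	c.1103G>A	p.Arg368His	Primary congenital glaucoma	P	AR	Carrier Risk	HGMD
TCIRG1	c.1674-1G>A	p.?	Infantile malignant osteopetrosis	P	AR	Carrier Risk	HGMD,LOF
LTBP4	c.254delT	p.Leu85ArgfsX15	Cutis laxa, autosomal recessive, type IC	P	AR	Carrier Risk	LOF
RAPSN	c.264C>A	p.Asn88Lys	Congenital myasthenic syndrome	P	AR	Carrier Risk	HGMD
TCTN2	c.1877T>A	p.Leu626X	Joubert syndrome	P	AR	Carrier Risk	LOF
DUOX2	c.2895_2898del	p.Phe966SerfsX29	Congenital hypothyroidism	P	AR	Carrier Risk	LOF
HFE	c.845G>A	p.Cys282Tyr	Hereditary hemochromatosis	P	AR	Carrier Risk	HGMD
GJB2	c.109G>A	p.Val37Ile	Hearing loss	P	AR	Carrier Risk	HGMD
RAB27A	c.259G>C	p.Ala87Pro	Familial hemophagocytic lymphohistiocytosis	VUS:FP	AR	Carrier Risk	HGMD
CNGA3	c.1669G>A	p.Gly557Arg	Achromatopsia	VUS:FP	AR	Carrier Risk	HGMD
KCNQ1	c.826delT	p.Ser276ProfsX13	Romano Ward syndrome	LP	AD	Monogenic	LOF
MYBPC3	c.3742-3759dup	p.Gly1248_Cys1253dup	Hypertrophic cardiomyopathy	LP	AD	Monogenic	HGMD
MYBPC3	c.2827C>T	p.Arg943X	Hypertrophic cardiomyopathy	P	AD	Monogenic	HGMD,LOF
MYBPC3	c.772G>A	p.Glu258Lys	Hypertrophic cardiomyopathy	P	AD	Monogenic	HGMD
LHX4	c.452-2A>C	p.?	Combined pituitary hormone deficiency	P	AD	Monogenic	LOF
PTPN11	c.1403C>T	p.Thr468Met	LEOPARD syndrome	P	AD	Monogenic	HGMD
PPOX	c.199delC	p.Leu67X	Variegate porphyria	P	AD	Monogenic	HGMD,LOF
MYH7	c.1987C>T	p.Arg663Cys	Hypertrophic cardiomyopathy	P	AD	Monogenic	HGMD
ARSE	c.410G>C	p.Gly137Ala	Chondrodysplasia punctata	VUS:FP	XL	Monogenic	HGMD
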