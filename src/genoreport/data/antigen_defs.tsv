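system	antigen	gene	chrom	pos	ref	alt	present_on	high_prevalence	immunogenic	disease_note
ABO	A	ABO	chrB1	1010	CG	C	abo_A	0	0	
ABO	B	ABO	chrB1	1020	G	A	abo_B	0	0	
RH	D	RHD	chrB1	2010	G	A	ref	0	1	
RH	C	RHCE	chrB1	3010	G	A	ref	0	0	
RH	c	RHCE	chrB1	3010	G	A	alt	0	0	
RH	e	RHCE	chrB1	3020	G	A	ref	0	0	
RH	E	RHCE	chrB1	3020	G	A	alt	0	0	
RH	Cw	RHCE	chrB1	3030	G	A	alt	0	0	
KEL	k	KEL	chrB1	4010	G	A	ref	1	0	
KEL	K	KEL	chrB1	4010	G	A	alt	0	1	
KEL	Kpb	KEL	chrB1	4020	G	A	ref	1	0	
KEL	Kpa	KEL	chrB1	4020	G	A	alt	0	0	
KEL	Jsb	KEL	chrB1	4030	G	A	ref	1	0	
KEL	Jsa	KEL	chrB1	4030	G	A	alt	0	0	
FY	Fya	ACKR1	chrB1	5010	G	A	ref	0	0	
FY	Fyb	ACKR1	chrB1	5010	G	A	alt	0	0	The Fy(a-b-) null phenotype is associated with resistance to Plasmodium vivax malaria.
JK	Jka	SLC14A1	chrB1	6010	G	A	ref	0	0	
JK	Jkb	SLC14A1	chrB1	6010	G	A	alt	0	0	
MNS	M	GYPA	chrB1	7010	G	A	ref	0	0	
MNS	N	GYPA	chrB1	7010	G	A	alt	0	0	
MNS	s	GYPB	chrB1	8010	G	A	ref	0	0	
MNS	S	GYPB	chrB1	8010	G	A	alt	0	0	
MNS	U	GYPB	chrB1	8020	G	A	ref	1	0	
LU	Lub	BCAM	chrB1	9010	G	A	ref	1	0	
LU	Lua	BCAM	chrB1	9010	G	A	alt	0	0	
DI	Dib	SLC4A1	chrB1	10010	G	A	ref	1	0	
DI	Dia	SLC4A1	chrB1	10010	G	A	alt	0	0	
DI	Wrb	SLC4A1	chrB1	10020	G	A	ref	1	0	
DI	Wra	SLC4A1	chrB1	10020	G	A	alt	0	0	
CO	Coa	AQP1	chrB1	11010	G	A	ref	1	0	
CO	Cob	AQP1	chrB1	11010	G	A	alt	0	0	
DO	Dob	ART4	chrB1	12010	G	A	ref	0	0	
DO	Doa	ART4	chrB1	12010	G	A	alt	0	0	
DO	Hy	ART4	chrB1	12020	G	A	ref	1	0	
DO	Joa	ART4	chrB1	12030	G	A	ref	1	0	
YT	Yta	ACHE	chrB1	13010	G	A	ref	1	0	
YT	Ytb	ACHE	chrB1	13010	G	A	alt	0	0	
SC	Sc1	ERMAP	chrB1	14010	G	A	ref	1	0	
SC	Sc2	ERMAP	chrB1	14010	G	A	alt	0	0	
LW	LWa	ICAM4	chrB1	15010	G	A	ref	1	0	
LW	LWb	ICAM4	chrB1	15010	G	A	alt	0	0	
CROM	Cra	CD55	chrB1	16010	G	A	ref	1	0	
KN	Kna	CR1	chrB1	17010	G	A	ref	1	0	
KN	Knb	CR1	chrB1	17010	G	A	alt	0	0	
KN	McCa	CR1	chrB1	17020	G	A	ref	1	0	
KN	Sl1	CR1	chrB1	17030	G	A	ref	1	0	
IN	Inb	CD44	chrB1	18010	G	A	ref	1	0	
IN	Ina	CD44	chrB1	18010	G	A	alt	0	0	
GE	Ge2	GYPC	chrB1	19010	G	A	ref	1	0	
GE	Ge3	GYPC	chrB1	19020	G	A	ref	1	0	
XK	Kx	XK	chrB1	20010	G	A	ref	1	0	Absence of Kx is associated with McLeod syndrome (acanthocytosis, late-onset neuromuscular findings).
VEL	Vel	SMIM1	chrB1	21010	G	A	ref	1	0	
LE	Leb	FUT3	chrB1	22010	G	A	ref	0	0	
LE	Lea	FUT3	chrB1	22020	G	A	alt	0	0	
P1PK	P1	A4GALT	chrB1	23010	G	A	ref	0	0	
JR	Jra	ABCG2	chrB1	24010	G	A	ref	1	0	
LAN	Lan	ABCB6	chrB1	25010	G	A	ref	1	0	
HPA	HPA-1a	ITGB3	chrB1	26010	G	A	ref	1	1	
HPA	HPA-1b	ITGB3	chrB1	26010	G	A	alt	0	0	
HPA	HPA-2a	GP1BA	chrB1	27010	G	A	ref	1	0	
HPA	HPA-2b	GP1BA	chrB1	27010	G	A	alt	0	0	
HPA	HPA-3a	ITGA2B	chrB1	28010	G	A	ref	0	0	
HPA	HPA-3b	ITGA2B	chrB1	28010	G	A	alt	0	0	
HPA	HPA-4a	ITGB3	chrB1	26020	G	A	ref	1	0	
HPA	HPA-4b	ITGB3	chrB1	26020	G	A	alt	0	0	
HPA	HPA-5a	ITGA2	chrB1	29010	G	A	ref	1	0	
HPA	HPA-5b	ITGA2	chrB1	29010	G	A	alt	0	0	
HPA	HPA-15a	CD109	chrB1	30010	G	A	ref	0	0	
HPA	HPA-15b	CD109	chrB1	30010	G	A	alt	0	0	
HPA	HPA-6bw	ITGB3	chrB1	26030	G	A	alt	0	0	
HPA	HPA-7bw	ITGB3	chrB1	26040	G	A	alt	0	0	
HPA	HPA-8bw	ITGB3	chrB1	26050	G	A	alt	0	0	
HPA	HPA-9bw	ITGA2B	chrB1	28020	G	A	alt	0	0	
HPA	HPA-10bw	ITGB3	chrB1	26060	G	A	alt	0	0	
HPA	HPA-11bw	ITGB3	chrB1	26070	G	A	alt	0	0	
HPA	HPA-12bw	GP1BB	chrB1	31010	G	A	alt	0	0	
HPA	HPA-13bw	ITGA2	chrB1	29020	G	A	alt	0	0	
HPA	HPA-14bw	ITGB3	chrB1	26080	G	A	alt	0	0	
HPA	HPA-16bw	ITGB3	chrB1	26090	G	A	alt	0	0	
HPA	HPA-17bw	ITGB3	chrB1	26100	G	A	alt	0	0	
HPA	HPA-18bw	ITGA2	chrB1	29030	G	A	alt	0	0	
HPA	HPA-19bw	ITGB3	chrB1	26110	G	A	alt	0	0	
HPA	HPA-20bw	ITGA2B	chrB1	28030	G	A	alt	0	0	
HPA	HPA-21bw	ITGB3	chrB1	26120	G	A	alt	0	0	
HPA	HPA-22bw	ITGA2B	chrB1	28040	G	A	alt	0	0	
HPA	HPA-23bw	ITGB3	chrB1	26130	G	A	alt	0	0	
HPA	HPA-24bw	ITGA2B	chrB1	28050	G	A	alt	0	0	
HPA	HPA-25bw	ITGA2	chrB1	29040	G	A	alt	0	0	
HPA	HPA-26bw	ITGB3	chrB1	26140	G	A	alt	0	0	
HPA	HPA-27bw	ITGA2B	chrB1	28060	G	A	alt	0	0	
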