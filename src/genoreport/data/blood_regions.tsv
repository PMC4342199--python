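gene	chrom	start	end
ABO	chrB1	1000	1999
RHD	chrB1	2000	2999
RHCE	chrB1	3000	3999
KEL	chrB1	4000	4999
ACKR1	chrB1	5000	5999
SLC14A1	chrB1	6000	6999
GYPA	chrB1	7000	7999
GYPB	chrB1	8000	8999
BCAM	chrB1	9000	9999
SLC4A1	chrB1	10000	10999
AQP1	chrB1	11000	11999
ART4	chrB1	12000	12999
ACHE	chrB1	13000	13999
ERMAP	chrB1	14000	14999
ICAM4	chrB1	15000	15999
CD55	chrB1	16000	16999
CR1	chrB1	17000	17999
CD44	chrB1	18000	18999
GYPC	chrB1	19000	19999
XK	chrB1	20000	20999
SMIM1	chrB1	21000	21999
FUT3	chrB1	22000	22999
A4GALT	chrB1	23000	23999
ABCG2	chrB1	24000	24999
ABCB6	chrB1	25000	25999
ITGB3	chrB1	26000	26999
GP1BA	chrB1	27000	27999
ITGA2B	chrB1	28000	28999
ITGA2	chrB1	29000	29999
CD109	chrB1	30000	30999
GP1BB	chrB1	31000	31999
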