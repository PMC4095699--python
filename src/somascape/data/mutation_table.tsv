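gene	cases	chromosome	change	protein	effect	mutation_type	polyphen2	gerp	rna_expression
TP53	5	17	GAA>CAA	p.E286Q	Missense	Transversion	1.00	.	Yes
TP53	5	17	ATG>ACG	p.M246T	Missense	Transition	1.00	.	Yes
TP53	5	17	GAG>AAG	p.E68K	Missense	Transition	0.09	.	ND
TP53	5	17	TAC>TGC	p.Y234C	Missense	Transition	0.97	.	ND
TP53	5	17	c.742_743insA	.	Frame shift	Ins/del	.	5.91	ND
DNAH9	4	17	A>G	.	Splice intron	Transition	.	4.05	No coverage
DNAH9	4	17	CGG>CAG	p.R2605Q	Missense	Transition	1.00	.	No coverage
DNAH9	4	17	ATG>ATA	p.M3430I	Missense	Transition	0.00	.	ND
DNAH9	4	17	CAG>TAG	p.Q3082*	Nonsense	Transition	.	4.05	ND
FBXO38	2	5	TAT>TGT	p.Y1058C	Missense	Transition	1.00	.	Yes
FBXO38	2	5	GAA>CAA	p.E20Q	Missense	Transversion	0.96	.	ND
THSD4	2	15	GAG>AAG	p.E476K	Missense	Transition	1.00	.	Yes
THSD4	2	15	GAG>AAG	p.E652K	Missense	Transition	0.96	.	ND
TRMT5	2	14	TTT>CTT	p.F303L	Missense	Transition	0.04	.	Yes
TRMT5	2	14	GAG>CAG	p.E152Q	Missense	Transversion	0.03	.	ND
PIK3CA	2	3	CTC>GTC	p.L540V	Missense	Transversion	0.99	.	ND
PIK3CA	2	3	CAG>CCG	p.Q546P	Missense	Transversion	1.00	.	ND
FOXO3	1	6	GCA>ACA	p.A267T	Missense	Transition	0.97	.	ND
FOXO3	1	6	CCT>TCT	p.P292S	Missense	Transition	0.34	.	ND
FOXO3	1	6	TTG>GTG	p.L528V	Missense	Transversion	0.03	.	ND
BBS12	1	4	CGC>TGC	p.R674C	Missense	Transition	1.00	.	Yes
BBS9	1	7	CCA>TCA	p.P77S	Missense	Transition	1.00	.	No coverage
CASP8AP2	1	6	GAT>AAT	p.D1420N	Missense	Transition	1.00	.	No coverage
EIF2B5	1	3	GCA>ACA	p.A406T	Missense	Transition	0.05	.	Yes
FMN2	1	1	GCT>CCT	p.A659P	Missense	Transversion	0.74	.	No coverage
HSP90B1	1	12	ACG>ATG	p.T468M	Missense	Transition	0.98	.	Yes
IKBKE	1	1	GAC>TAC	p.D571Y	Missense	Transversion	0.68	.	Yes
PCF11	1	11	AAT>AGT	p.N167S	Missense	Transition	0.02	.	Yes
PLCL1	1	2	AAG>AAT	p.K279N	Missense	Transversion	0.98	.	No coverage
PTPN21	1	14	CGA>CTA	p.R864L	Missense	Transversion	1.00	.	Yes
SEC63	1	6	CGC>TGC	p.R217C	Missense	Transition	1.00	.	ND
SPTLC3	1	20	G>A	.	Splice intron	Transition	.	5.91	No coverage
ST7L	1	1	GAT>GCT	p.D339A	Missense	Transversion	1.00	.	Yes
SYNRG	1	17	ATG>ATA	p.M970I	Missense	Transition	0.45	.	Yes
UBR4	1	1	AAC>AAA	p.N3400K	Missense	Transversion	0.98	.	Yes
ZFYVE26	1	14	CAA>CCA	p.Q1582P	Missense	Transversion	0.00	.	Yes
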