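kindred	gene	transcript	hgvs_c	hgvs_p	zygosity	inheritance	gnomad_af
FPOI1	STAG3	NM_001282717	c.2301+2T>G	.	biallelic	AR	0.0000006195
FPOI2	MCM9	NM_017696.3	c.1217C>T	p.A406V	biallelic	AR	0.00000062
FPOI2	XRCC1	NM_006297.3	c.482C>A	p.P161Q	biallelic	.	0.00000063
FPOI3	PSMC3IP	NM_016556.4	c.35-2A>G	.	biallelic	AR	0.00000000
FPOI4	POLR2C	NM_032940.3	c.670G>A	p.G224S	monoallelic	Polygenic	0.00001492
FPOI4	ANKRD31	NM_001372053.1	c.3641G>C	p.S1214T	monoallelic	.	0.00005914
FPOI4	PCSK1	NM_000439.5	c.548delC	p.P183Qfs	monoallelic	.	0.00000000
FPOI4	STAG3	NM_001282717.2	c.1437_1446del	p.Q479Hfs	monoallelic	.	0.00000000
FPOI4	TP63	NM_001329146.2	c.97G>A	p.G33S	monoallelic	.	0.00007249
FPOI4	WRN	NM_000553.6	c.1957C>G	p.L653V	monoallelic	.	0.00000744
FPOI5	ZSWIM7	NM_001042697.2	c.173C>G	p.S58*	biallelic	AR	0.00000000
FPOI6	YTHDC2	NM_022828.5	c.2567C>G	p.P856R	biallelic	AR	0.00000000
FPOI7	NLRP11	NM_001394894.2	c.2318C>G	p.P773R	monoallelic	AD	0.00000186
FPOI8	PLEC	NM_201384.3	c.5933A>C	p.E1978A	monoallelic	CH	0.00005263
FPOI8	PLEC	NM_201384.3	c.-98T>G	.	monoallelic	.	0.00001377
FPOI9	IGSF10	NM_178822.5	c.5996dup	p.S2000Ifs	monoallelic	AD	0.00015780
FPOI10	PRKD1	NM_002742.3	c.724G>T	p.G242C	monoallelic	AD	0.00028700
FPOI11	PDE3A	NM_000921.5	c.1210A>C	p.N404H	monoallelic	Polygenic	0.00003942
FPOI11	POLR3H	NM_001018050.4	c.445C>T	p.R149C	monoallelic	.	0.00005913
FPOI11	MSH6	NM_000179.3	c.1508C>G	p.S503C	monoallelic	.	0.00054560
FPOI11	CLPP	NM_006012.4	c.411G>C	p.Q137H	monoallelic	.	0.00000434
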