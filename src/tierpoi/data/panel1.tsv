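gene	category	tier	expected_inheritance	source_note
FSHR	1	green	biallelic	curated POI panel
GDF9	1	green	biallelic,monoallelic	curated POI panel
MCM9	1	green	biallelic	curated POI panel
PRDM9	1	green	monoallelic	curated POI panel
BMP15	1	green	monoallelic	curated POI panel; X-linked
NBN	1	green	biallelic,monoallelic	curated POI panel
NOBOX	1	green	biallelic	curated POI panel
STAG3	1	green	biallelic	curated POI panel
LARS2	1	green	biallelic	curated POI panel
MCM8	1	green	biallelic	curated POI panel
EIF4ENIF1	1	amber	monoallelic	curated POI panel
BUB1B	1	amber	monoallelic	curated POI panel
PSMC3IP	1	amber	biallelic	curated POI panel
POLR2C	1	amber	monoallelic	curated POI panel
FOXO4	1	red	monoallelic	curated POI panel; X-linked
ATM	1	red	monoallelic	curated POI panel
YTHDC2	1	red	biallelic	curated POI panel
ZSWIM7	1	red	biallelic	curated POI panel
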