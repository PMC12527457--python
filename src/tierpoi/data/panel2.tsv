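gene	category	tier	expected_inheritance	source_note
XRCC1	2	none		literature POI gene
ANKRD31	2	none		literature POI gene
PCSK1	2	none		literature POI gene
TP63	2	none		literature POI gene
WRN	2	none		literature POI gene
NLRP11	2	none		literature POI gene
PLEC	2	none		literature POI gene
IGSF10	2	none		literature POI gene
PRKD1	2	none		literature POI gene
PDE3A	2	none		literature POI gene
POLR3H	2	none		literature POI gene
MSH6	2	none		literature POI gene
CLPP	2	none		literature POI gene
HELQ	2	none		literature POI gene
MLH1	2	none		literature POI gene
ATG7	2	none		literature POI gene
GREM1	2	none		literature POI gene
AMH	2	none		literature POI gene
BRCA2	2	none		literature POI gene
SETX	2	none		literature POI gene
DCAF17	2	none		literature POI gene
FANCM	2	none		literature POI gene
MEIOB	2	none		literature POI gene
PRDM1	2	none		literature POI gene
SALL4	2	none		literature POI gene
GJA4	2	none		literature POI gene
FANCF	2	none		literature POI gene
BMP8B	2	none		literature POI gene
ZNF462	2	none		literature POI gene
GHR	2	none		literature POI gene
BMPR2	2	none		literature POI gene
BNC1	2	none		literature POI gene
FANCL	2	none		literature POI gene
SYCP1	2	none		literature POI gene
LLGL1	2	none		literature POI gene
NRIP1	2	none		literature POI gene
ESR1	2	none		literature POI gene
INSL3	2	none		literature POI gene
PATL2	2	none		literature POI gene
SUN1	2	none		literature POI gene
LHX8	2	none		literature POI gene
RNF212	2	none		literature POI gene
BLM	2	none		literature POI gene
MEI1	2	none		literature POI gene
ZP1	2	none		literature POI gene
IRS4	2	none		literature POI gene; X-linked
FSHB	2	none		literature POI gene
MACF2	2	none		literature POI gene
SMC1B	2	none		literature POI gene
DMC1	2	none		literature POI gene
TSC2	2	none		literature POI gene
KIT	2	none		literature POI gene
REC8	2	none		literature POI gene
MLH3	2	none		literature POI gene
UBR2	2	none		literature POI gene
EXO1	2	none		literature POI gene
FIGNL1	2	none		literature POI gene
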