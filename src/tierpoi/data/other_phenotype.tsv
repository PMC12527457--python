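gene	phenotype
PKD1L1	situs inversus
ABCA4	rod-cone retinal dystrophy
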