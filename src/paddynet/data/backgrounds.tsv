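metal	background_mg_kg	provenance
Cd	0.11	Taihu regional background (reported)
Pb	20.78	Taihu regional background (reported)
Cu	22.3	back-solved from printed PLI of YX_1/YX_8 (synthetic constant)
Zn	62.6	back-solved from printed PLI of YX_1/YX_8 (synthetic constant)
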