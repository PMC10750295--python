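YAPTAZ_TARGETS_22	editable 22-gene YAP/TAZ target signature; replace with your curated list	CCN1	CCN2	ANKRD1	AMOTL2	AXL	THBS1	SERPINE1	FOSL1	TOP2A	MYBL2	DKK1	NT5E	GADD45A	MARCKS	FJX1	PTX3	RHOB	NUAK2	TGFB2	ARHGEF17	CRIM1	DOCK5
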