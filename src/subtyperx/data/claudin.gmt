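CLDN	claudin quartet used for the CLDN score	CLDN3	CLDN4	CLDN7	CDH1
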