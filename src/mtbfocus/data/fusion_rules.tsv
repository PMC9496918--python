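# Characteristic fusion -> tumor-entity reassignment rules (gene pair
# matched unordered by default).
gene5	gene3	entity
TMPRSS2	ERG	prostate carcinoma
SEC31A	ALK	ALK-positive DLBCL
CLDN18	ARHGAP26	gastric carcinoma
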