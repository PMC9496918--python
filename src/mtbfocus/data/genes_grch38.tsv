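# GRCh38 gene intervals (0-based half-open) for the copy-number annotation
# examples and tests.
gene	contig	start	end
ARID1A	chr1	26696015	26782104
NRAS	chr1	114704464	114716894
PDGFRA	chr4	54229293	54298245
KIT	chr4	54657918	54740715
KDR	chr4	55078481	55125595
FBXW7	chr4	152320544	152536063
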