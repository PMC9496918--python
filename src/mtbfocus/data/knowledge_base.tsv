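# Local evidence knowledge base: alteration patterns with therapy, ESCAT
# tier, DKTK evidence level and label status. Empty tier fields mean the
# recommendation is standard-of-care (no molecular tier applies).
gene	alteration	entity	therapy	escat	dktk	label	early_phase_trial
ATM	deletion	acinic cell carcinoma	Niraparib + Carboplatin	III-B	m4	off	0
BRAF	V600E	CRC	Encorafenib + Binimetinib + Cetuximab	I-A	m1a	off	0
ARID1A	deletion	sinonasal adenocarcinoma	Pembrolizumab	III-A	m2b	off	0
RET	Y791F	steroid cell tumor	Cabozantinib	IV-A	m3	off	0
BRAF	V600E	CUP	Encorafenib + Binimetinib	III-A	m2a	off	0
EGFR	amplification	TNBC	Cetuximab + Capecitabine	IV-A	m1c	off	0
KDR	amplification	sarcoma	Pazopanib	IV-A	m3	on	0
KIT	amplification	sarcoma	Pazopanib	IV-A	m3	on	0
PDGFRA	amplification	sarcoma	Pazopanib	IV-A	m3	on	0
EML4-ALK	fusion	pancreatic carcinoma	Alectinib	III-B	m4	off	0
FGFR2-ARHGAP24	fusion	cholangiocarcinoma	Pemigatinib	III-A	m2a	off	0
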