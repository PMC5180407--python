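# gene5	gene3	labels (semicolon-separated; bundled default subset)
BCR	ABL1	diagnostic;targetable
ETV6	NTRK3	diagnostic;targetable
EWSR1	FLI1	diagnostic
EWSR1	WT1	diagnostic
PAX7	FOXO1	diagnostic;prognostic
PAX3	FOXO1	diagnostic;prognostic
NUP214	ABL1	prognostic;targetable
FOXP1	ABL1	prognostic;targetable
CBFB	MYH11	prognostic
CBFA2T3	GLIS2	diagnostic;prognostic
ASPSCR1	TFE3	diagnostic
C11orf95	RELA	diagnostic;prognostic
NUP98	NSD1	prognostic;targetable
KMT2A	AFF1	prognostic;targetable
TMEM106B	BRAF	targetable
SMARCC2	PDGFRB	targetable
VCAN	IL23R	targetable
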