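target	alteration	drug	approval_status	pediatric_dosing	evidence_class	tumor_types
BCR-ABL1	*	imatinib	approved	yes	clinical	cml;all
ETV6-NTRK3	*	crizotinib	approved	yes	preclinical	congenital fibrosarcoma;infantile fibrosarcoma
NUP214-ABL1	*	dasatinib	approved	yes	preclinical	all
FOXP1-ABL1	*	dasatinib	approved	yes	preclinical	all
NUP98-NSD1	*	pinometostat	experimental	yes	preclinical	aml
KMT2A-AFF1	*	pinometostat	experimental	yes	preclinical	aml
TMEM106B-BRAF	*	trametinib	approved	yes	clinical	melanoma
SMARCC2-PDGFRB	*	imatinib	approved	yes	preclinical	all
VCAN-IL23R	*	ruxolitinib	approved	yes	preclinical	other
KIT	*	imatinib	approved	yes	clinical	aml
IDH1	p.R132C	enasidenib analog	experimental	yes	clinical	aml
TET2	*	azacitidine	approved	yes	clinical	aml
FLT3	p.D835E	sorafenib	approved	yes	clinical	aml
SMARCA4	*	tazemetostat	experimental	yes	clinical	atypical teratoid rhabdoid tumor
SMARCB1	*	tazemetostat	experimental	yes	preclinical	hepatic rhabdoid tumor;atypical teratoid rhabdoid tumor
TSC1	*	everolimus	approved	yes	clinical	subependymal giant cell astrocytoma
PIK3CA	*	alpelisib analog	experimental	yes	clinical	breast carcinoma
NRAS	*	trametinib	approved	yes	preclinical	aml;all;neuroblastoma;rhabdomyosarcoma
KRAS	*	trametinib	approved	yes	preclinical	aml;all;neuroblastoma
KRAS	p.V14I	trametinib	approved	yes	preclinical	other
JAK3	*	ruxolitinib	approved	yes	preclinical	aml
JAK1	*	ruxolitinib	approved	yes	preclinical	other
PTPN11	*	trametinib	approved	yes	preclinical	aml
MYC	*	JQ1 analog	experimental	yes	preclinical	osteosarcoma
KMT2C	*	JQ1 analog	experimental	yes	preclinical	other
STAT5B	*	navitoclax	experimental	yes	preclinical	other
H3F3A	p.K28M	panobinostat	experimental	yes	preclinical	glioma
FGFR4	*	ponatinib	approved	yes	preclinical	rhabdomyosarcoma
CDK2	*	palbociclib	approved	yes	preclinical	glioblastoma multiforme
PTCH1	*	vismodegib	approved	yes	preclinical	medulloblastoma
SUFU	*	vismodegib	approved	yes	preclinical	medulloblastoma
ALK	p.Q1146K	crizotinib	approved	yes	preclinical	neuroblastoma
RAD51C	*	olaparib	approved	yes	preclinical	other
CDK4	*	palbociclib	approved	yes	preclinical	neuroblastoma
PDGFRA	*	sorafenib	approved	yes	preclinical	osteosarcoma
KDR	*	sorafenib	approved	yes	preclinical	osteosarcoma
CUL4A	*	pevonedistat	experimental	yes	preclinical	osteosarcoma
MCL1	*	palbociclib	approved	yes	preclinical	osteosarcoma
CCNE1	*	palbociclib	approved	yes	preclinical	osteosarcoma
EGFR	*	erlotinib	approved	no	clinical	nsclc
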