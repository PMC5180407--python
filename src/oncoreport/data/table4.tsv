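section	patient_id	diagnosis	gene	mutation	change	mutation_type	clinical_utility	implication	previously_known	same_patient
hematologic	14-19751	HLH	MLL2	c.11640_11640delG; c.15631G>A	p.M3881Cfs*9 (de novo); p.E5211K	Compound heterozygous, frameshift	Diagnostic	Kabuki syndrome; Transplantation withheld	No	0
hematologic	15-90485	HLH	C1QA	c.622C>T	p.Gln208Ter	Homozygous, nonsense	Diagnostic	C1Q deficiency	No	0
hematologic	15-33031	MDS	GATA2	c.16delG	p.(E6fs)	Heterozygous, frameshift	Supports transplant recommendation; Genetic counseling for family	Increased risk for developing AML and MDS	No	0
hematologic	14-92247	ALL	PMS2	c.1376C>G	p.S459X	Homozygous, missense	Diagnostic; Health maintenance/Genetic counseling	Constitutional mismatch repair deficiency syndrome; Lynch syndrome (parents)	No	0
hematologic	15-46877	HLH	XIAP	c.1328G>C	p.R443P	Missense	Diagnostic	X-linked lymphoproliferative syndrome 2 (XLP2); Transplantation recommended	No	0
hematologic	14-19750	AML	RUNX1	c.806-2A>G	r.Spl?	Heterozygous splice site	Diagnostic	Familial platelet disorder; Transplantation donor changed from sibling to unrelated donor	No	0
solid	14-56374	Hepatoblastoma	APC	c.3340C>T	p.R1114	Nonsense	Diagnostic; Health maintenance/Genetic counseling	Familial adenomatous polyposis	Yes	0
solid	15-33544	Poorly differentiated carcinoma with focal neuroendocrine differentiation	APC	c.4660_4661insA	p.E1554fs	Frameshift	Diagnostic; Health maintenance/Genetic counseling	Gardner syndrome; Familial adenomatous polyposis	No	0
solid	15-35162	Osteosarcoma	RB1	c.1216-3A>G	p.?	Splice site	Health maintenance/Genetic counseling	Increased risk for developing other cancers	Yes	0
solid	15-44470	Medulloblastoma	ATM	c.566G>A; c.8266A>T	p.R189K; p.K2756*	Missense, nonsense	Health maintenance/Genetic counseling	Increased risk for developing other cancers	No	0
solid	15-78886	Pineoblastoma	UGT1A1	*28 allele ("(TA)7TAA")		Homozygous	Pharmacogenomic	Drug sensitivity	No	1
solid	15-78886	Pineoblastoma	DICER1	c.4807dupC	p.L1603Pfs	Frameshift	Health maintenance/Genetic counseling	Risk of ovarian Sertoli-Leydig cell tumor	No	1
solid	15-17264	Hepatocellular carcinoma	UGT1A1	*28 allele		Heterozygous	Pharmacogenomic	Drug sensitivity	No	0
acmg	15-29224	AML	TP53	c.644G>A	p.S215N	Missense	Affects therapy; Health maintenance/Genetic counseling	Explains lack of response to conventional therapy; Increased risk for developing other cancers	No	0
acmg	14-59462	Nested stromal epithelial tumor of the liver	BRCA1	c.68_69delAG	p.Glu23Valfs	Frameshift	Health maintenance/Genetic counseling	Breast cancer	No	0
acmg	16-88073	Ependymoma	BRCA1	c.5587_5594delGTAGCACT	p.V1863Lfs*35	Frameshift	Health maintenance/Genetic counseling	Breast cancer	No	0
acmg	14-75899	Neuroblastoma	RYR1	c.6838G>A	p.V2280I	Missense	Health maintenance/Genetic counseling	Malignant hyperthermia	No	0
acmg	14-13487	Osteosarcoma	TNNT2	c.422G>A	p.Arg141Gln	Heterozygous	Health maintenance/Genetic counseling	Dilated cardiomyopathy	No	0
acmg	15-34296	Ependymoma	VHL	c.539T>C	p.I180T	Missense	Health maintenance/Genetic counseling	Von Hippel Lindau syndrome	No	0
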