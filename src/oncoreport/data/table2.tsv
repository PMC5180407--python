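section	patient_id	diagnosis	alteration	mutation	therapy	same_patient	therapy_received
tier1	14-85546	CML	BCR-ABL1	Fusion	TKI	0	0
tier1	13-45348	AML	IDH1	c.394C>T (p.R132C)	IDH Inhibitor	1	0
tier1	14-24794	AML	c-KIT; TET2; FLT3	c.2446G>C (p.D816H); c.3663delT (p.C1221Wfs); c.2505T>G (p.D835E)	TKI; Hypomethylating agent; TKI	1	0
tier1	14-53198	AML	TET2	c.1156G>T (p.V386L)	Hypomethylating agent	0	0
tier1	13-77086	AML	c-KIT	c.1965T>G (p.Asn655Lys)	TKI	0	1
tier2	15-18928	Hepatic rhabdoid tumor	SMARCA4	c.3574C>T (p.R1192C)	EZH2 Inhibitor	0	0
tier2	14-13487	Osteosarcoma	TSC1	c.2503-1G>C (p.?)	mTOR Inhibitor	0	0
tier2	14-47205	Nephroblastomatosis	PIK3CA	c.1035T>A (p.N345K)	PI3K/AKT/mTOR Inhibitor	0	0
tier2	15-40141	Pleomorphic xanthoastrocytoma	TMEM106B-BRAF	Fusion	MEK Inhibitor	0	0
tier3	15-64793	ALL	FOXP1-ABL1	Fusion	TKI	0	1
tier3	15-26188	ALL	NUP214-ABL1	Fusion	TKI	0	1
tier3	15-79700	ALL	NRAS	c.183A>T (p.Q61H)	MEK Inhibitor	0	0
tier3	14-20062	ALL	KRAS	c.183A>T (p.Q61H)	MEK Inhibitor	0	0
tier3	14-24794	AML	NRAS	c.183A>C (p.Q61H)	MEK Inhibitor	1	0
tier3	15-29224	AML	JAK3	c.1718C>T (p.A573V)	JAK Inhibitor	0	0
tier3	13-45348	AML	NRAS	c.38G>C (p.G13A)	MEK Inhibitor	1	0
tier3	13-95124	AML	NRAS; MLL-AFF1 (KMT2A-AFF1)	c.182A>G (p.Q61R); Fusion	MEK Inhibitor; DOT1L Inhibitor	0	0
tier3	14-45760	AML	NRAS	c.38G>A (p.G13D)	MEK Inhibitor	0	0
tier3	13-50662	AML	PTPN11	c.1508G>T (p.G503V)	MEK Inhibitor	0	0
tier3	14-15491	AML	NUP98-NSD1	Fusion	DOT1L Inhibitor	0	0
tier3	14-27243	Neuroblastoma	NRAS	c.181C>A (p.Q61K)	MEK Inhibitor	0	0
tier3	14-70449	Rhabdomyosarcoma	NRAS	c.181C>A (p.Q61K)	MEK Inhibitor	0	0
tier3	14-42817	Neuroblastoma	KRAS	c.34G>T (p.G12C)	MEK Inhibitor	0	0
tier3	15-11925	Osteosarcoma	MYC	Overexpression	BET Inhibitor	1	0
tier3	16-74654	Rhabdomyosarcoma	FGFR4	c.1582G>T (p.G528C); c.1648G>C (p.V550L)	FGFR4 Inhibitor	0	0
tier3	15-23518	Rhabdomyosarcoma	FGFR4	c.1648G>C (p.V550L); c.1949G>T (p.R650L); Overexpression	FGFR4 Inhibitor	0	0
tier3	14-37237	Glioblastoma multiforme	Gain 12q.14.1 involving CDK2	Copy number	CDK4/6 Inhibitor	0	0
tier3	15-44470	Medulloblastoma	PTCH1, SUFU, ZIC3	Overexpression	SMO Inhibitor	0	0
tier3	15-10838	Glioma	H3F3A; FGFR1	c.83A>T (p.K28M); c.1731C>A (p.N577K)	HDAC Inhibitor	0	0
tier3	15-27992	Hepatic rhabdoid tumor	Homozygous deletion of chr 22q11.23 with homozygous deletion of SMARCB1; Loss of expression of SMARCB1	Copy number; Loss of expression with biallelic deletion	EZH2 Inhibitor	0	0
tier4	15-36388	AML	MLL3 (KMT2C)	c.2110G>T (p.E704X)	BET Inhibitor	0	0
tier4	13-72282	T-ALL	KRAS; JAK1; STAT5B	c.40G>A (p.V14I); c.3076A>G (p.K1026E); c.2110A>C (p.I704L)	MEK Inhibitor; JAK Inhibitor; BCL2/BCLX-L Inhibitor	0	0
tier4	15-66870	Adrenocortical carcinoma	ALK	c.3436C>A (p.Q1146K)	ALK Inhibitor	0	1
tier5	15-16072	ALL	SMARCC2-PDGFRB	Fusion	TKI	0	0
tier5	14-75899	Neuroblastoma	CDK4, MDM2	Overexpression	NEPENTHE trial [NCT02780128]	0	0
tier5	15-11925	Osteosarcoma	MCL1, CCNE1	Overexpression	CDK4/6 Inhibitor	1	0
tier5	15-35162	Osteosarcoma	CUL4A	Overexpression	NAE Inhibitor	0	0
tier5	14-71727	Osteosarcoma	RAD51C	c.24T>G (p.F8L)	PARP Inhibitor	0	0
tier5	15-83826	Osteosarcoma	PDGFRA, KDR (VEGFR2)	Overexpression	MTKI	0	1
tier5	13-21968	Congenital fibrosarcoma	EML4-NTRK3	Fusion	ALK Inhibitor	0	0
tier5	14-84044	Inflammatory myofibroblastic tumor	VCAN-IL23R	Fusion	JAK Inhibitor	0	1
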