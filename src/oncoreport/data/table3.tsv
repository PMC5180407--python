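section	patient_id	diagnosis	alteration	mutation	clinical_utility	implication	same_patient
sequence_mutations	15-63375	AML changed to JMML	PTPN11; SETB1	c.181G>T (p.D61Y); c.2602G>A (p.D868N)	Diagnostic	JMML	0
sequence_mutations	13-72282	T-ALL	STAT5B	c.2110A>C (p.I704L)	Diagnostic	Gamma-delta T-cell lymphoma	1
sequence_mutations	15-26188	ALL	NT5C2	c.1219G>T (p.D407Y)	Pharmacogenomic	Affects therapy	0
sequence_mutations	13-45348	AML	IDH1	c.394C>T (p.R132C)	Diagnostic	Maffucci syndrome	0
sequence_mutations	14-53198	AML	CEBPA	c.939_940insAAG (p.K313_V314insK); c.326_327insC (p.P109fs)	Prognostic	Improved prognosis	0
sequence_mutations	15-10838	Glioma	H3F3A	c.83A>T (p.K28M)	Prognostic	Poor prognosis	0
sequence_mutations	14-37237	Glioblastoma multiforme	H3F3A	c.83A>T (p.K28M)	Prognostic	GBM subgroup, K27	0
sequence_mutations	14-35585	Renal cell carcinoma	VHL	c.497T>G (p.V166G)	Diagnostic	Von Hippel Lindau	0
sequence_mutations	14-47205	Nephroblastomatosis	PIK3CA	c.1035T>A (p.N345K)	Diagnostic	Nephroblastomatosis	0
sequence_mutations	14-78154	Medulloblastoma	KDM6A	c.2989_2990dupAT (p.M997fs)	Prognostic	Risk stratification, group 4	1
sequence_mutations	14-75899	Neuroblastoma	ATRX	c.5239delA (p.T1747fs)	Prognostic	Poor prognosis	0
sequence_mutations	14-10141	Pleuropulmonaryblastoma	DICER1	c.5438A>G (p.E1813G)	Health Maintenance	DICER syndrome	0
transcriptome_cnv	14-24794	AML	CBFB-MYH11	Fusion	Prognostic	Low-risk stratification	0
transcriptome_cnv	15-64793	B-ALL	FOXP1-ABL1	Fusion	Prognostic	High-risk stratification	0
transcriptome_cnv	15-84578	AMKL	CBFA2T3-GLIS2	Fusion	Diagnostic; Prognostic	AMKL; Poor prognosis	0
transcriptome_cnv	14-85546	CML	BCR-ABL1	Fusion	Diagnostic	CML	0
transcriptome_cnv	13-72282	T-ALL	Isochromosome 7q	Copy number change	Diagnostic	Gamma-delta T-cell lymphoma	1
transcriptome_cnv	15-46387	Rhabdomyosarcoma	PAX7-FOXO1	Fusion	Diagnostic; Prognostic	Rhabdomyosarcoma; High-risk group	0
transcriptome_cnv	13-81192	Alveolar soft part sarcoma	ASPSCR1-TFE3	Fusion	Diagnostic	Alveolar soft part sarcoma	0
transcriptome_cnv	13-65217	Ewing sarcoma	EWSR1-FLI1	Fusion	Diagnostic	Ewing sarcoma	0
transcriptome_cnv	15-47087	Ewing sarcoma	EWSR1-FLI1; Low expression of PAX8, FHIT, CASP10, CHD2, with high expression of CHD11, FUS, and MTA1	Fusion; Expression pattern	Diagnostic; Prognostic	Ewing sarcoma; Poor prognosis	0
transcriptome_cnv	13-21968	Undifferentiated sarcoma	EML4-NTRK3	Fusion	Diagnostic	Infantile fibrosarcoma	0
transcriptome_cnv	16-88073	Ependymoma	C11orf95-RELA; Alternating gains and losses on chr 11 and 22, consistent with a "chromothripsis-like" pattern	Fusion; Copy number change	Prognostic; Diagnostic	Poor prognosis; RELA-type supratentorial ependymoma	0
transcriptome_cnv	14-27243	Neuroblastoma	MYCN amplified, deletion at 1p and 11q, gain 17q; MYCN over expressed	Copy number change; Overexpression	Prognostic	Risk-based therapy	0
transcriptome_cnv	14-42817	Neuroblastoma	MYCN non-amplified, no LOH at 1p11q; MYCN not over expressed	Copy number change; No overexpression	Prognostic	Risk-based therapy	0
transcriptome_cnv	15-39486	Neuroblastoma	MYCN non-amplified, no LOH at 1p11q; MYCN not over expressed	Copy number change; No overexpression	Prognostic	Risk-based therapy	0
transcriptome_cnv	14-44070	Neuroblastoma	MYCN amplified, loss of 1p, gain of 1q and 17q; MYCN over expressed	Copy number change; Overexpression	Prognostic	Risk-based therapy	0
transcriptome_cnv	15-88980	Hepatoblastoma	Amplification of 11q13.2 including CCND1; Over expression of CCND1	Copy number change; Overexpression	Prognostic	Good prognosis	0
transcriptome_cnv	15-49177	Medulloblastoma	IMPG2, GABRA5, LAPTM4B, MAB21L2, NPR3, MFAP4, NRL, ZFPM2, TSHZ3, IGF2BP3, GALNT14, GPR98; Loss of 10q22.2-10qter involving PTEN and SUFU, loss of 17p, gain of 17q	Overexpression; Copy number change	Prognostic	Risk stratification, subgroup 3/4	0
transcriptome_cnv	15-70532	Ependymoma	Gain of 1q, loss of 6q	Copy number change	Prognostic	Poor prognosis	0
transcriptome_cnv	14-78154	Medulloblastoma	KCNA1, RBM24, KLHL13, EN2, SNCAIP, PDE1C, GRM8, KCNIP4, EXPH5, UNC5D, NID2, ST18, GPR12, SH3GL3; i17q	Overexpression; Copy number change	Prognostic	Risk stratification, subgroup 4	1
transcriptome_cnv	15-40141	Pleomorphic xanthoastrocytoma	Gain of chromosome 7, LOH at 9p	Copy number change	Diagnostic	Pleomorphic xanthoastrocytoma	0
transcriptome_cnv	15-97336	Small round blue cell tumor	EWSR1-WT1	Fusion	Diagnostic	DSRCT	0
transcriptome_cnv	15-34296	Ependymoma	TNC, CALB1, PLAG1, ALDH1L1, RELN	Overexpression	Prognostic	Risk stratification, group A, poor prognosis	0
transcriptome_cnv	15-80972	ATRT	LOH at 22q11.21qter, including SMARCB1; ASCL1	Copy number change; Overexpression	Diagnostic; Prognostic	ATRT; Improved prognosis	0
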