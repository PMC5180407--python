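# Well-established cancer genes (bundled default subset)
ABL1
ALK
APC
ATM
ATRX
BRAF
BRCA1
BRCA2
CDK4
CDKN2A
CEBPA
DICER1
EGFR
FGFR1
FGFR4
FLT3
GATA2
H3F3A
IDH1
IDH2
ITK
JAK1
JAK2
JAK3
KDM6A
KIT
KMT2A
KMT2C
KMT2D
KRAS
MDM2
MYC
MYCN
NF1
NRAS
NTRK3
PDGFRA
PDGFRB
PIK3CA
PMS2
PTCH1
PTEN
PTPN11
RAD51C
RB1
RUNX1
SDHC
SMARCA4
SMARCB1
STAT5B
SUFU
TET2
TP53
TSC1
TSC2
VHL
WT1
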