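# Cancer predisposition + pharmacogenomics genes (bundled default subset)
ALK
APC
ATM
BRCA1
BRCA2
C1QA
CBL
CEBPA
CYP2C19
CYP2D6
DICER1
DPYD
G6PD
GATA2
ITK
KMT2D
MLL2
MLH1
MSH2
MSH6
NF1
NF2
NT5C2
NUDT15
PHOX2B
PMS2
PRF1
PTCH1
PTPN11
RB1
RUNX1
SDHA
SDHB
SDHC
SDHD
SH2D1A
SMARCA4
SMARCB1
STX11
STXBP2
SUFU
TP53
TPMT
UGT1A1
UNC13D
VHL
WT1
XIAP
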