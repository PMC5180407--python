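# gene	hgvs_p  (recurrent driver changes; bundled default subset)
IDH1	p.R132C
IDH1	p.R132H
KIT	p.D816H
KIT	p.D816V
KIT	p.Asn655Lys
FLT3	p.D835E
FLT3	p.D835Y
NRAS	p.Q61K
NRAS	p.Q61H
NRAS	p.Q61R
NRAS	p.G13A
NRAS	p.G13D
NRAS	p.G12D
KRAS	p.G12C
KRAS	p.G12D
KRAS	p.G12V
KRAS	p.Q61H
PIK3CA	p.N345K
PIK3CA	p.E545K
PIK3CA	p.H1047R
H3F3A	p.K28M
H3F3A	p.G35R
PTPN11	p.G503V
PTPN11	p.D61Y
FGFR4	p.V550L
FGFR4	p.G528C
JAK3	p.A573V
BRAF	p.V600E
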