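# gene	hgvs_c  (variants relevant to patient care; bundled default subset)
UGT1A1	*28
NT5C2	c.1219G>T
TPMT	c.719A>G
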