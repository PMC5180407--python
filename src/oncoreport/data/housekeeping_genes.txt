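# Housekeeping genes used for expression normalization (bundled default
# subset; the production catalog holds ~8000 symbols)
ACTB
B2M
CHMP2A
EEF1A1
EMC7
GAPDH
GPI
GUSB
HMBS
HPRT1
PGK1
POLR2A
PPIA
PSMB4
RAB7A
REEP5
RPL13A
RPL32
RPLP0
RPS18
RPS29
SDHA
SNRPD3
TBP
TFRC
TUBB
UBC
VCP
VPS29
YWHAZ
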