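# COSMIC catalog identifiers (bundled default subset)
COSM512
COSM521
COSM532
COSM554
COSM564
COSM580
COSM1135366
COSM28746
COSM28747
COSM1140132
COSM1311
COSM1314
COSM763
COSM775
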