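TssA	active
TssAFlnk	active
TxFlnk	active
Tx	active
TxWk	active
EnhG	active
Enh	active
ZNF/Rpts	inactive
Het	inactive
TssBiv	inactive
BivFlnk	inactive
EnhBiv	inactive
ReprPC	inactive
ReprPCWk	inactive
Quies	inactive
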