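TssA	tss
TssAFlnk	tss
TxFlnk	transcription
Tx	transcription
TxWk	transcription
EnhG	enhancer
Enh	enhancer
ZNF/Rpts	heterochromatin
Het	heterochromatin
TssBiv	bivalent
BivFlnk	bivalent
EnhBiv	bivalent
ReprPC	heterochromatin
ReprPCWk	heterochromatin
Quies	heterochromatin
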