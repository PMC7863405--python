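# Roadmap 18-state mnemonics -> 6 super states (editable data, echoed into
# output metadata by the pipeline)
TssA	Promoter
TssFlnk	Promoter
TssFlnkU	Promoter
TssFlnkD	Promoter
Tx	Transcription
TxWk	Transcription
EnhG1	Enhancer
EnhG2	Enhancer
EnhA1	Enhancer
EnhA2	Enhancer
EnhWk	Enhancer
ZNF/Rpts	Heterochromatin
Het	Heterochromatin
TssBiv	Bivalent/Polycomb
EnhBiv	Bivalent/Polycomb
ReprPC	Bivalent/Polycomb
ReprPCWk	Bivalent/Polycomb
Quies	Quiescent
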