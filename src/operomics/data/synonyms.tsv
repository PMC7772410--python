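variant	canonical
Methionine—tRNA ligase	Methionyl-tRNA synthetase
Methionine-tRNA ligase	Methionyl-tRNA synthetase
AAA ATPase	AAA+ ATPase
Cell division protein SepF	Cell division inhibitor
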