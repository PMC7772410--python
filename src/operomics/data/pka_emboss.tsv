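group	pka	charge
Nterm	8.6	positive
Cterm	3.6	negative
C	8.5	negative
D	3.9	negative
E	4.1	negative
H	6.5	positive
K	10.8	positive
R	12.5	positive
Y	10.1	negative
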