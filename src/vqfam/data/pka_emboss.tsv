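# EMBOSS iep default pKa set; alternative table for sensitivity checks.
group	kind	pka
Nterm	base	8.6
Cterm	acid	3.6
D	acid	3.9
E	acid	4.1
C	acid	8.5
Y	acid	10.1
H	base	6.5
K	base	10.8
R	base	12.5
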