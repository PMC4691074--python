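# Bjellqvist pKa set as used by the ExPASy ProtParam pI calculator.
# kind: acid (deprotonation releases negative charge) or base (protonated form
# positive); nterm/cterm rows override the terminus pKa when the chain starts
# or ends with that residue (part of the original calibration).
group	kind	pka
Nterm	base	7.5
Cterm	acid	3.55
D	acid	4.05
E	acid	4.45
C	acid	9.0
Y	acid	10.0
H	base	5.98
K	base	10.0
R	base	12.0
A	nterm	7.59
M	nterm	7.0
S	nterm	6.93
P	nterm	8.36
T	nterm	6.82
V	nterm	7.44
E	nterm	7.7
G	nterm	7.5
D	cterm	4.55
E	cterm	4.75
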