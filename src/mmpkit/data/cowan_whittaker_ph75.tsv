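# Cowan & Whittaker (1990) HPLC-derived residue hydrophobicity at pH 7.5
# residue	score
A	0.35
R	-1.50
N	-0.44
D	-2.15
C	0.76
Q	-0.93
E	-1.95
G	0.00
H	-0.65
I	1.83
L	1.80
K	-1.54
M	1.10
F	1.69
P	0.84
S	-0.63
T	-0.27
W	1.35
Y	0.39
V	1.32
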