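# Average amino acid frequencies (percent) over UniProtKB/Swiss-Prot,
# offered as an optional background composition for the synthetic fixture
# generator (the default background is uniform 1/20).
residue	percent
A	8.25
C	1.38
D	5.45
E	6.72
F	3.86
G	7.07
H	2.27
I	5.91
K	5.80
L	9.65
M	2.41
N	4.06
P	4.74
Q	3.93
R	5.53
S	6.65
T	5.36
V	6.85
W	1.10
Y	2.92
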