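# Per-residue composition (c), polarity (p) and molecular volume (v) from
# Grantham's 1974 amino acid difference table. The chemical distance between
# residues i and j is
#     D_ij = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)
# with alpha=1.833, beta=0.1018, gamma=0.000399 and rho chosen so the mean of
# the 190 pairwise distances is 100. The loader reconstructs the full matrix;
# it reproduces the published distances to rounding (e.g. I-L=5, C-W=215,
# D-E=45, R-K=26).
residue	composition	polarity	volume
A	0.00	8.1	31.0
C	2.75	5.5	55.0
D	1.38	13.0	54.0
E	0.92	12.3	83.0
F	0.00	5.2	132.0
G	0.74	9.0	3.0
H	0.58	10.4	96.0
I	0.00	5.2	111.0
K	0.33	11.3	119.0
L	0.00	4.9	111.0
M	0.00	5.7	105.0
N	1.33	11.6	56.0
P	0.39	8.0	32.5
Q	0.89	10.5	85.0
R	0.65	10.5	124.0
S	1.42	9.2	32.0
T	0.71	8.6	61.0
V	0.00	5.9	84.0
W	0.13	5.4	170.0
Y	0.20	6.2	136.0
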