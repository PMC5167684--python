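# Eight physicochemical property scales from the AAindex database, keyed by
# AAindex accession. One row per residue (canonical 20-letter alphabet),
# one column per scale. Values cross-checked against the aaindex data set
# shipped with the seqinr R package.
#   CIDH920105  normalized average hydrophobicity
#   BHAR880101  average flexibility indices
#   CHAM820101  polarizability parameter
#   CHAM820102  free energy of solution in water
#   CHOC760101  residue accessible surface area in tripeptide
#   BIGC670101  residue volume
#   CHAM810101  steric parameter
#   DAYM780201  relative mutability
residue	CIDH920105	BHAR880101	CHAM820101	CHAM820102	CHOC760101	BIGC670101	CHAM810101	DAYM780201
A	0.02	0.357	0.046	-0.368	115	52.6	0.52	100
C	0.77	0.346	0.128	4.530	135	68.3	0.62	20
D	-1.04	0.511	0.105	2.060	150	68.4	0.76	106
E	-1.14	0.497	0.151	1.770	190	84.7	0.68	102
F	1.35	0.314	0.290	1.060	210	113.9	0.70	41
G	-0.80	0.544	0.000	-0.525	75	36.3	0.00	49
H	0.26	0.323	0.230	0.000	195	91.9	0.70	66
I	1.81	0.462	0.186	0.791	175	102.0	1.02	96
K	-0.41	0.466	0.219	0.000	200	105.1	0.68	56
L	1.14	0.365	0.186	1.070	170	102.0	0.98	40
M	1.00	0.295	0.221	0.656	185	97.7	0.78	94
N	-0.77	0.463	0.134	0.000	160	75.7	0.76	134
P	-0.09	0.509	0.131	-2.240	145	73.6	0.36	56
Q	-1.10	0.493	0.180	0.731	180	89.7	0.68	93
R	-0.42	0.529	0.291	-1.030	225	109.1	0.68	65
S	-0.97	0.507	0.062	-0.524	115	54.9	0.53	120
T	-0.77	0.444	0.108	0.000	140	71.2	0.50	97
V	1.13	0.386	0.140	0.401	155	85.1	0.76	74
W	1.71	0.305	0.409	1.600	255	135.4	0.70	18
Y	1.11	0.420	0.298	4.910	230	116.2	0.70	41
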