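# Single-bond covalent radii by element (Angstrom).
# Source: Cordero et al., Dalton Trans. (2008) 2832.
element	radius
H	0.31
C	0.76
N	0.71
O	0.66
F	0.57
P	1.07
S	1.05
CL	1.02
BR	1.20
I	1.39
SE	1.20
FE	1.32
ZN	1.22
MG	1.41
CA	1.76
MN	1.39
NA	1.66
K	2.03
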