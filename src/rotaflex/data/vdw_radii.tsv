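# Van der Waals radii by element (Angstrom).
# Source: A. Bondi, J. Phys. Chem. 68 (1964) 441, with the common 1.70 A
# carbon value; applied uniformly to protein and ligand atoms.
element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
CL	1.75
BR	1.85
I	1.98
SE	1.90
B	1.92
SI	2.10
FE	1.50
ZN	1.39
MG	1.73
CA	1.75
MN	1.60
NA	2.27
K	2.75
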