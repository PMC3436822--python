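# Canonical chi dihedral atom quadruples, standard PDB v3 atom names.
# One row per (residue type, chi index); atoms are ordered a1-a2-a3-a4.
residue	chi	a1	a2	a3	a4
ARG	1	N	CA	CB	CG
ARG	2	CA	CB	CG	CD
ARG	3	CB	CG	CD	NE
ARG	4	CG	CD	NE	CZ
ASN	1	N	CA	CB	CG
ASN	2	CA	CB	CG	OD1
ASP	1	N	CA	CB	CG
ASP	2	CA	CB	CG	OD1
CYS	1	N	CA	CB	SG
GLN	1	N	CA	CB	CG
GLN	2	CA	CB	CG	CD
GLN	3	CB	CG	CD	OE1
GLU	1	N	CA	CB	CG
GLU	2	CA	CB	CG	CD
GLU	3	CB	CG	CD	OE1
HIS	1	N	CA	CB	CG
HIS	2	CA	CB	CG	ND1
ILE	1	N	CA	CB	CG1
ILE	2	CA	CB	CG1	CD1
LEU	1	N	CA	CB	CG
LEU	2	CA	CB	CG	CD1
LYS	1	N	CA	CB	CG
LYS	2	CA	CB	CG	CD
LYS	3	CB	CG	CD	CE
LYS	4	CG	CD	CE	NZ
MET	1	N	CA	CB	CG
MET	2	CA	CB	CG	SD
MET	3	CB	CG	SD	CE
PHE	1	N	CA	CB	CG
PHE	2	CA	CB	CG	CD1
PRO	1	N	CA	CB	CG
PRO	2	CA	CB	CG	CD
SER	1	N	CA	CB	OG
THR	1	N	CA	CB	OG1
TRP	1	N	CA	CB	CG
TRP	2	CA	CB	CG	CD1
TYR	1	N	CA	CB	CG
TYR	2	CA	CB	CG	CD1
VAL	1	N	CA	CB	CG1
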