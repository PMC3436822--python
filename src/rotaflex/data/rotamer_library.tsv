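# Backbone-independent side-chain rotamer table in the Penultimate style:
# modal chi angles (degrees) per rotamer with a +/-30 degree admission window
# unless per-chi half-widths are given.  Rotamer names follow the p/t/m
# (gauche+/trans/gauche-) convention.  Frequencies are approximate population
# fractions used only for deterministic tie-breaking.
# chis / half_widths are comma-separated, one value per chi torsion.
residue	rotamer	chis	half_widths	frequency
ARG	mtt180	-67,180,180,180		0.09
ARG	mtt85	-67,180,180,85		0.06
ARG	mtt-85	-67,180,180,-85		0.07
ARG	mtm180	-67,180,-65,180		0.05
ARG	ttt180	-177,180,180,180		0.06
ARG	ttp85	-177,180,65,85		0.04
ARG	mmt180	-62,-68,180,180		0.05
ARG	ptt180	62,180,180,180		0.03
ASN	m-40	-65,-40		0.29
ASN	m120	-65,120		0.07
ASN	t-20	-174,-20		0.12
ASN	t30	-177,30		0.09
ASN	p-10	62,-10		0.13
ASN	p30	62,30		0.07
ASP	m-20	-70,-15		0.51
ASP	t0	-177,0		0.22
ASP	t70	-177,65		0.09
ASP	p-10	62,-10		0.14
CYS	m	-65		0.50
CYS	t	-177		0.26
CYS	p	62		0.23
GLN	mt-30	-67,180,-25		0.16
GLN	mm-40	-65,-65,-40		0.14
GLN	mm100	-65,-65,100		0.05
GLN	tt0	-177,180,0		0.12
GLN	tp60	-177,65,60		0.04
GLN	pt20	62,180,20		0.05
GLU	mt-10	-67,180,-10		0.25
GLU	mm-40	-65,-65,-40		0.12
GLU	tt0	-177,180,0		0.14
GLU	tp10	-177,65,10		0.05
GLU	pt-20	62,180,-20		0.06
GLU	mp0	-65,85,0		0.04
HIS	m-70	-65,-70		0.29
HIS	m170	-65,165		0.13
HIS	m80	-65,80		0.13
HIS	t-80	-177,-80		0.11
HIS	t60	-177,60		0.16
HIS	p80	62,80		0.07
HIS	p-80	62,-75		0.09
ILE	mt	-65,170		0.60
ILE	mm	-57,-60		0.15
ILE	pt	62,170		0.13
ILE	tt	-177,166		0.08
LEU	mt	-65,175		0.59
LEU	tp	-177,65		0.29
LEU	mp	-85,65		0.02
LEU	tt	-172,145		0.02
LYS	mttt	-67,180,180,180		0.20
LYS	tttt	-177,180,180,180		0.13
LYS	mttp	-67,180,180,65		0.05
LYS	mttm	-67,180,180,-65		0.05
LYS	mmtt	-62,-68,180,180		0.06
LYS	mtmt	-67,180,-68,180		0.04
LYS	pttt	62,180,180,180		0.04
LYS	tttp	-177,180,180,65		0.04
MET	mmm	-65,-65,-70		0.19
MET	mtp	-67,180,75		0.19
MET	mtm	-67,180,-75		0.11
MET	ttp	-177,180,75		0.10
MET	ttm	-177,180,-75		0.07
MET	mtt	-67,180,180		0.05
MET	tpp	-177,65,75		0.03
PHE	m-85	-65,-85		0.44
PHE	m-30	-65,-30		0.09
PHE	t80	-177,80		0.33
PHE	p90	62,90		0.13
PRO	endo	27,-35		0.44
PRO	exo	-27,36		0.56
SER	p	62		0.48
SER	t	-177		0.22
SER	m	-65		0.29
THR	p	62		0.49
THR	t	-175		0.07
THR	m	-65		0.43
TRP	m95	-65,95		0.32
TRP	m-90	-65,-90		0.26
TRP	m-5	-65,-5		0.05
TRP	t-105	-177,-105		0.16
TRP	t90	-177,90		0.14
TRP	p-90	62,-90		0.11
TYR	m-85	-65,-85		0.44
TYR	m-30	-65,-30		0.09
TYR	t80	-177,80		0.33
TYR	p90	62,90		0.13
VAL	t	175		0.73
VAL	m	-60		0.20
VAL	p	63		0.06
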