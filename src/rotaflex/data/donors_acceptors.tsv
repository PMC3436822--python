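# Side-chain N/O hydrogen-bond roles for the residues whose side chains are
# counted in the H-bond statistics (strong N/O...N/O bonds only).
residue	atom	role
ARG	NE	donor
ARG	NH1	donor
ARG	NH2	donor
ASN	ND2	donor
ASN	OD1	acceptor
ASP	OD1	acceptor
ASP	OD2	acceptor
GLN	NE2	donor
GLN	OE1	acceptor
GLU	OE1	acceptor
GLU	OE2	acceptor
HIS	ND1	both
HIS	NE2	both
LYS	NZ	donor
SER	OG	both
THR	OG1	both
TRP	NE1	donor
TYR	OH	both
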