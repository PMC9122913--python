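# Protein-reactive chemistry patterns, v1: electrophiles and oxidizers that
# covalently modify or oxidize protein residues (a structural stand-in for a
# reactivity assay). name<TAB>class<TAB>SMARTS. Matching any pattern fails.
acyl_halide	acylator	[CX3](=[OX1])[F,Cl,Br,I]
sulfonyl_halide	acylator	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
anhydride	acylator	[CX3](=[OX1])[OX2][CX3](=[OX1])
isocyanate	acylator	[NX2]=[CX2]=[OX1]
isothiocyanate	acylator	[NX2]=[CX2]=[SX1]
aldehyde	acylator	[CX3H1](=O)[#6]
alkyl_halide	alkylator	[CX4;!$(C(F)(F)F)][Cl,Br,I]
epoxide	alkylator	[CX4]1[OX2][CX4]1
aziridine	alkylator	[CX4]1[NX3][CX4]1
michael_acceptor	michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
quinone	oxidizer	O=C1C=CC(=O)C=C1
peroxide	oxidizer	[OX2][OX2]
n_halamine	oxidizer	[#7][Cl,Br,I]
diazonium	alkylator	[N+]#N
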