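# Curated frequent-hitter (PAINS-family) substructure patterns, v1.
# A compact subset of the well-known pan-assay interference motif families,
# written as SMARTS; name<TAB>SMARTS. Matching any pattern fails the screen.
rhodanine_core	O=C1[CH2]SC(=S)N1
thiazolidinone_2_4	O=C1[CH2]SC(=O)N1
catechol	[OX2H]c1ccccc1[OX2H]
hydroquinone	[OX2H]c1ccc([OX2H])cc1
quinone_para	O=C1C=CC(=O)C=C1
quinone_ortho	O=C1C(=O)C=CC=C1
azo_aryl	c[NX2]=[NX2]c
hydrazone_aryl	c[CX3H0,CX3H1]=[NX2][NX3]
ene_rhodanine	C=C1SC(=S)NC1=O
alkylidene_barbiturate	C=C1C(=O)NC(=O)NC1=O
aminothiophene_ester	c1cc(sc1N)C(=O)O[CH3,CH2]
isothiazolone	O=C1C=CSN1
phenol_mannich	[OX2H]c1ccccc1[CH2][NX3]
beta_aminoketone_aryl	cC(=O)[CH2][CH2][NX3]
imine_phenol	[OX2H]c1ccccc1C=[NX2]
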