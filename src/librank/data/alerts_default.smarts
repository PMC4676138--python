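# Default promiscuous-binder / frequent-HTS-hitter substructure catalog.
# PAINS-style classes written as auditable SMARTS; replace or extend freely.
# Format: name<TAB>SMARTS, one per line, '#' starts a comment.
catechol	[OX2H1]c1ccccc1[OX2H1]
hydroquinone	[OX2H1]c1ccc([OX2H1])cc1
quinone_para	O=C1C=CC(=O)C=C1
quinone_ortho	O=C1C(=O)C=CC=C1
rhodanine	S=C1NC(=O)CS1
ene_rhodanine	S=C1NC(=O)C(=[CX3])S1
michael_acceptor_enone	[CX3;!R]=[CX3][CX3]=[OX1]
alkyl_halide	[CX4;!$(C(F)(F)F)][Cl,Br,I]
azo	[#6][NX2]=[NX2][#6]
nitro_aromatic	c[N+](=O)[O-]
isothiazolone	O=C1C=CSN1
acyl_hydrazone	[NX3][NX2]=[CX3H1]
thiourea	[NX3][CX3](=S)[NX3]
aromatic_aldehyde	c[CX3H1]=O
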