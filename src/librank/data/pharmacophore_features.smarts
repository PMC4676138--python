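# Pharmacophoric feature definitions used by the topological n-point
# pharmacophore fingerprints. Format: feature_type<TAB>SMARTS; a type may
# span several lines (union of patterns); '#' starts a comment.
donor	[NX3;H1,H2;+0]
donor	[NX4;H1,H2,H3;+1]
donor	[OX2;H1]
donor	[nX3;H1]
acceptor	[OX2;H0;+0]
acceptor	[OX1;$([OX1]=[CX3,SX4,PX4,NX3])]
acceptor	[OX1-]
acceptor	[NX2;H0;+0;!$(N=N)]
acceptor	[nX2;+0]
acceptor	[NX3;H0;+0;!$(N-a);!$(N-[C,S,P]=[O,S,N])]
pos_ionizable	[NX4;+1]
pos_ionizable	[NX3;+0;!$(N=*);!$(N-a);!$(N-[C,S,P]=[O,S,N])]
pos_ionizable	[NX2;+0]=[CX3][NX3]
neg_ionizable	[OX1-]
neg_ionizable	[OX2H1][CX3]=[OX1]
neg_ionizable	[OX2H1][SX4](=[OX1])=[OX1]
neg_ionizable	[OX2H1][PX4]=[OX1]
aromatic	a
hydrophobe	[C;!$(C~[#7,#8,#9,#15,#16,Cl,Br,I]);!$(C=,#*)]
halogen	[F,Cl,Br,I]
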