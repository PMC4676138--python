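# Rule table for (de)protonation of standard ionizable groups at pH 7.4.
# Columns (tab separated): name, kind {acid,base}, pKa, SMARTS.
# The FIRST atom of the SMARTS is the site that gains (base) or loses (acid)
# a proton. Acids with pKa < 7.4 are deprotonated; bases with pKa > 7.4 are
# protonated. Patterns are written so that the transformed group no longer
# matches, which makes the pass idempotent.
carboxylic_acid	acid	4.2	[OX2H1][CX3]=[OX1]
sulfonic_acid	acid	-1.0	[OX2H1][SX4](=[OX1])=[OX1]
sulfinic_acid	acid	2.0	[OX2H1][SX3]=[OX1]
phosphonic_acid	acid	2.0	[OX2H1][PX4]=[OX1]
aliphatic_amine	base	10.0	[NX3;H0,H1,H2;+0;!$(N=*);!$(N-a);!$(N-[C,S,P]=[O,S,N]);!$(N-[NX2]);!$(N-C#N)]
amidine_guanidine	base	12.0	[NX2;H0,H1;+0]=[CX3;$(C[#6]),$(C[NX3])][NX3;+0]
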