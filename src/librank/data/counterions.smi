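# Common counter-ions and small salt partners recognised during salt
# stripping. One SMILES per line; matching is by canonical SMILES of the
# detached fragment. '#' starts a comment.
[Cl-]
Cl
[Br-]
Br
[I-]
I
[F-]
[Na+]
[K+]
[Li+]
[Ca+2]
[Mg+2]
[Zn+2]
[NH4+]
N
O
O=C(O)C(=O)O
OC(=O)C(=O)[O-]
CC(=O)O
CC(=O)[O-]
OC(=O)/C=C/C(=O)O
OC(=O)/C=C\C(=O)O
CS(=O)(=O)O
CS(=O)(=O)[O-]
Cc1ccc(S(=O)(=O)O)cc1
Cc1ccc(S(=O)(=O)[O-])cc1
OS(=O)(=O)O
OS(=O)(=O)[O-]
O=S(=O)([O-])[O-]
O[N+](=O)[O-]
OP(=O)(O)O
OC(=O)C(O)C(O)C(=O)O
OCC(O)C(O)C(O)C(O)CO
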