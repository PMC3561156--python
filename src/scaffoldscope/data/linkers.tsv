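# smiles	name  (empty smiles = direct ring-ring bond; attachment atoms are the first and last written atom)
	direct_bond
C	methylene
CC	ethylene
CCC	propylene
O	ether
N	amine
CO	methyleneoxy
CN	methyleneamino
C=C	vinylene
C(=O)	carbonyl
C(=O)N	amide
S	thioether
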