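# smiles	name  (attachment atom is the first written atom)
C	methyl
CC	ethyl
CCC	propyl
C(C)C	isopropyl
O	hydroxy
OC	methoxy
N	amino
NC	methylamino
F	fluoro
Cl	chloro
Br	bromo
C(=O)O	carboxyl
C(=O)N	carboxamide
C#N	cyano
OCC	ethoxy
C(F)(F)F	trifluoromethyl
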