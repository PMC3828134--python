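# Functional-point typing table: one row per pseudoatom emitted for a
# residue.  The point is placed at the centroid of the listed atoms that
# are present in the residue; a row with no atom present is skipped.
# Columns: residue<TAB>ptype<TAB>comma-separated atom names.
# ptype alphabet: donor, acceptor, mixed, aromatic, aliphatic.
ARG	donor	NH1,NH2,NE,CZ
LYS	donor	NZ
HIS	donor	ND1
HIS	mixed	ND1,NE2
HIS	aromatic	CG,ND1,CD2,CE1,NE2
ASP	acceptor	OD1,OD2,CG
GLU	acceptor	OE1,OE2,CD
ASN	acceptor	OD1
ASN	mixed	ND2
GLN	acceptor	OE1
GLN	mixed	NE2
SER	mixed	OG
THR	mixed	OG1
TYR	mixed	OH
PHE	aromatic	CG,CD1,CD2,CE1,CE2,CZ
TYR	aromatic	CG,CD1,CD2,CE1,CE2,CZ
TRP	aromatic	CD2,CE2,CE3,CZ2,CZ3,CH2
ALA	aliphatic	CB
VAL	aliphatic	CB,CG1,CG2
LEU	aliphatic	CB,CG,CD1,CD2
ILE	aliphatic	CB,CG1,CG2,CD1
MET	aliphatic	CB,CG,SD,CE
PRO	aliphatic	CB,CG,CD
CYS	aliphatic	CB,SG
GLY	aliphatic	CA
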