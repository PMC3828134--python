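# Het codes treated as non-specific ligands (crystallization additives,
# cryoprotectants, buffers, common counter-ions).  One code per line;
# lines starting with '#' are comments.  Edit freely: whether e.g. PO4
# or a metal is a genuine ligand depends on the protein under study.
SO4
PO4
GOL
EDO
PEG
PG4
P6G
PGE
MPD
DMS
ACT
ACY
FMT
TRS
EPE
MES
BME
CIT
NO3
AZI
IOD
BR
CL
NA
K
CS
HOH
WAT
DOD
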