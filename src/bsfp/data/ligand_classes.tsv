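# Het-code -> ligand class for annotation tables.  Polymer ligands are
# classified by residue content (DNA/RNA/peptide) before this table is
# consulted; everything unlisted falls through to "other".
ATP	nucleotide
ADP	nucleotide
AMP	nucleotide
ANP	nucleotide
AGS	nucleotide
GTP	nucleotide
GDP	nucleotide
GMP	nucleotide
GNP	nucleotide
GSP	nucleotide
CTP	nucleotide
CDP	nucleotide
CMP	nucleotide
UTP	nucleotide
UDP	nucleotide
UMP	nucleotide
U5P	nucleotide
TTP	nucleotide
TMP	nucleotide
DTP	nucleotide
NAD	nucleotide
NAI	nucleotide
NDP	nucleotide
NAP	nucleotide
FAD	nucleotide
FMN	nucleotide
SAM	nucleotide
SAH	nucleotide
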