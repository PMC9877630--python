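# name	recognition	top_cut_offset	bottom_cut_offset
# Offsets count nucleotides 3' of the recognition sequence on each strand;
# negative offsets place the cut inside the recognition sequence.
BsaI	GGTCTC	1	5
HindIII	AAGCTT	-5	-1
XbaI	TCTAGA	-5	-1
EcoRI	GAATTC	-5	-1
SacI	GAGCTC	-1	-5
SacII	CCGCGG	-2	-4
PstI	CTGCAG	-1	-5
BamHI	GGATCC	-5	-1
XhoI	CTCGAG	-5	-1
SalI	GTCGAC	-5	-1
PmeI	GTTTAAAC	-4	-4
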