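# Common type-II restriction endonucleases for CAPS marker screening.
# name	site (IUPAC, 5'->3' top strand)	cut offset on top strand
AciI	CCGC	1
AluI	AGCT	2
ApoI	RAATTY	1
BamHI	GGATCC	1
BstNI	CCWGG	2
DdeI	CTNAG	1
DraI	TTTAAA	3
EcoRI	GAATTC	1
EcoRV	GATATC	3
HaeIII	GGCC	2
HhaI	GCGC	3
HindIII	AAGCTT	1
HinfI	GANTC	1
HpaII	CCGG	1
KpnI	GGTACC	5
MseI	TTAA	1
MspI	CCGG	1
NdeI	CATATG	2
PstI	CTGCAG	5
RsaI	GTAC	2
SalI	GTCGAC	1
Sau3AI	GATC	0
SmaI	CCCGGG	3
TaqI	TCGA	1
XbaI	TCTAGA	1
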