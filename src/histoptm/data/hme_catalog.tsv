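symbol	class	substrates	notes
KAT2A	acetyltransferase	H3K9;H3K14	GCN5; GNAT family, SAGA/ATAC complexes, preferred H3K9/K14 writer
KAT2B	acetyltransferase	H3K9;H3K14	PCAF; GNAT family, mutually exclusive with KAT2A in SAGA-type complexes
KAT5	acetyltransferase	H3K14;H4K16	TIP60; MYST family, NuA4 complex
KAT6A	acetyltransferase	H3K9;H3K23	MOZ; MYST family
KAT6B	acetyltransferase	H3K23	MORF; MYST family
KAT7	acetyltransferase	H3K14;H4K12	HBO1; MYST family, H3K14 via JADE/BRPF scaffolds
KAT8	acetyltransferase	H4K16	MOF; MYST family, MSL/NSL complexes
CREBBP	acetyltransferase	H3K18;H3K27	CBP; KAT3A
EP300	acetyltransferase	H3K18;H3K27	p300; KAT3B
NCOA1	acetyltransferase	H3K9;H3K14	SRC1/KAT13A; nuclear receptor coactivator with reported HAT activity
NCOA2	acetyltransferase	H3K9;H3K14	TIF2/KAT13C; putative
NCOA3	acetyltransferase	H3K9;H3K14	ACTR/KAT13B; putative
TAF1	acetyltransferase	H3K14	TFIID subunit
GTF3C4	acetyltransferase	H3K14	TFIIIC90; reported H3K14-directed activity
CLOCK	acetyltransferase	H3K9;H3K14	circadian regulator with HAT activity
ELP3	acetyltransferase	H3K14	Elongator complex subunit
GOT2	acetyltransferase	H3K9;H3K14	putative; reported histone-directed acetyl transfer
HDAC1	deacetylase	H3K9;H3K14;H3K18;H3K27	class I; Sin3/NuRD/CoREST
HDAC2	deacetylase	H3K9;H3K14;H3K18;H3K27	class I
HDAC3	deacetylase	H3K9;H3K14;H3K18;H3K27	class I; SMRT/NCoR
HDAC4	deacetylase	H3K9;H3K14	class IIa
HDAC5	deacetylase	H3K9;H3K14	class IIa
HDAC6	deacetylase	H3K9;H3K14	class IIb; mostly cytoplasmic
HDAC7	deacetylase	H3K9;H3K14	class IIa
HDAC8	deacetylase	H3K9;H3K14	class I
HDAC9	deacetylase	H3K9;H3K14	class IIa
HDAC10	deacetylase	H3K9;H3K14	class IIb
HDAC11	deacetylase	H3K9;H3K14	class IV
SIRT1	deacetylase	H3K9;H3K14;H4K16	class III, NAD-dependent
SIRT2	deacetylase	H3K18;H4K16	class III
SIRT3	deacetylase	H3K9;H4K16	class III; also mitochondrial
SIRT4	deacetylase	H3K9	class III; putative histone activity
SIRT5	deacetylase	H3K9	class III; putative histone activity
SIRT6	deacetylase	H3K9;H3K18	class III
SIRT7	deacetylase	H3K18	class III
KMT2A	methyltransferase	H3K4	MLL1
KMT2B	methyltransferase	H3K4	MLL2/MLL4
KMT2C	methyltransferase	H3K4	MLL3
KMT2D	methyltransferase	H3K4	MLL4/MLL2
KMT2E	methyltransferase	H3K4	MLL5; putative
SETD1A	methyltransferase	H3K4	Set1 complex
SETD1B	methyltransferase	H3K4	Set1 complex
SETD7	methyltransferase	H3K4	SET7/9; monomethyl
PRDM9	methyltransferase	H3K4;H3K36	meiotic recombination hotspot writer
SMYD1	methyltransferase	H3K4	SMYD family
SMYD2	methyltransferase	H3K4;H3K36	SMYD family
SMYD3	methyltransferase	H3K4	SMYD family
SETD2	methyltransferase	H3K36	sole H3K36me3 writer
NSD1	methyltransferase	H3K36	me1/me2
NSD2	methyltransferase	H3K36	WHSC1/MMSET
NSD3	methyltransferase	H3K36	WHSC1L1
ASH1L	methyltransferase	H3K36	trithorax-related
SETMAR	methyltransferase	H3K36	Metnase; putative
SETD3	methyltransferase	H3K36	putative histone activity (canonical substrate is actin)
SUV39H1	methyltransferase	H3K9	me2/me3, heterochromatin
SUV39H2	methyltransferase	H3K9	me2/me3
EHMT1	methyltransferase	H3K9	GLP; me1/me2
EHMT2	methyltransferase	H3K9	G9a; me1/me2
SETDB1	methyltransferase	H3K9	ESET; me3
SETDB2	methyltransferase	H3K9	CLLD8
PRDM2	methyltransferase	H3K9	RIZ1
EZH1	methyltransferase	H3K27	PRC2
EZH2	methyltransferase	H3K27	PRC2
DOT1L	methyltransferase	H3K79	non-SET-domain
KMT5A	methyltransferase	H4K20	SET8/PR-Set7; me1
KMT5B	methyltransferase	H4K20	SUV420H1; me2/me3
KMT5C	methyltransferase	H4K20	SUV420H2; me2/me3
KDM1A	demethylase	H3K4;H3K9	LSD1; FAD-dependent, me1/me2
KDM1B	demethylase	H3K4	LSD2
KDM2A	demethylase	H3K36	JHDM1A
KDM2B	demethylase	H3K4;H3K36	JHDM1B
KDM3A	demethylase	H3K9	JMJD1A; me1/me2
KDM3B	demethylase	H3K9	JMJD1B
KDM4A	demethylase	H3K9;H3K36	JMJD2A; me2/me3
KDM4B	demethylase	H3K9;H3K36	JMJD2B
KDM4C	demethylase	H3K9;H3K36	JMJD2C
KDM4D	demethylase	H3K9	JMJD2D
KDM5A	demethylase	H3K4	JARID1A; me2/me3
KDM5B	demethylase	H3K4	JARID1B
KDM5C	demethylase	H3K4	JARID1C
KDM5D	demethylase	H3K4	JARID1D
KDM6A	demethylase	H3K27	UTX
KDM6B	demethylase	H3K27	JMJD3
KDM7A	demethylase	H3K9;H3K27	KIAA1718; me1/me2
PHF8	demethylase	H3K9;H4K20	KDM7B
PHF2	demethylase	H3K9	KDM7C
KDM8	demethylase	H3K36	JMJD5; putative
JMJD6	demethylase	H3R2;H4R3	reported arginine demethylase; putative
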