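refseq_human	refseq_rabbit	gene_name	description	similarity_pct	chromosome
XP_054183011	XP_051689653	ANOS1	anosmin-1	59.2	Unplaced
XP_054183834	XP_051683595	APOO	MICOS complex subunit MIC26	85.4	X
XP_054182860	XP_051687539	ATP11C	phospholipid-transporting ATPase IG	97.3	Unplaced
XP_016884870	XP_008271374	ATP1B4	protein ATP1B4	87.0	X
XP_016885042	XP_051693419	ATP2B3	plasma membrane calcium-transporting ATPase 3	90.5	Unplaced
NP_001174	NP_001164848	ATP6AP1	V-type proton ATPase subunit S1 precursor	90.4	Unplaced
NP_000045	XP_008248538	AVPR2	vasopressin V2 receptor	86.0	Unplaced
NP_001132929	XP_008248542	BCAP31	B-cell receptor-associated protein 31	92.7	Unplaced
XP_054183538	XP_051693405	BGN	biglycan	94.0	Unplaced
XP_047298518	XP_008273252	CD99L2	CD99 antigen-like protein 2	76.5	Unplaced
NP_005131	XP_051689801	CNGA2	cyclic nucleotide-gated olfactory channel	94.0	Unplaced
XP_011544483	XP_008273625	CRLF2	cytokine receptor-like factor 2	47.9	Unplaced
XP_047297804	XP_008249542	CSF2RA	granulocyte-macrophage colony-stimulating factor receptor subunit alpha	49.6	Unplaced
NP_001017978	XP_008271135	CT83	kita-kyushu lung cancer antigen 1	50.5	X
XP_006724531	XP_051683632	DMD	dystrophin	94.6	X
XP_054182733	XP_051689815	GABRA3	gamma-aminobutyric acid receptor subunit alpha-3	89.7	Unplaced
XP_011529486	XP_002721381	GABRQ	gamma-aminobutyric acid receptor subunit theta	84.7	Unplaced
XP_054182809	XP_002720349	GPC3	glypican-3	91.3	X
NP_473362	XP_017205202	GPR101	probable G-protein-coupled receptor 101	84.8	X
NP_848566	XP_002720339	GPR119	glucose-dependent insulinotropic receptor	85.1	X
XP_054183230	XP_008270867	GPR173	probable G-protein-coupled receptor 173	100.0	X
XP_005272654	XP_002719905	GPR34	probable G-protein-coupled receptor 34	90.9	X
XP_011529518	XP_008273247	GPR50	melatonin-related receptor	74.7	Unplaced
XP_047297947	XP_051682990	GPR82	probable G-protein-coupled receptor 82	90.8	X
XP_054183006	XP_008271141	IL13RA1	interleukin-13 receptor subunit alpha-1	83.8	X
XP_054183007	XP_051683230	IL13RA2	interleukin-13 receptor subunit alpha-2	65.7	X
XP_011529207	XP_008271052	IL1RAPL2	X-linked interleukin-1 receptor accessory protein-like 2	95.4	X
XP_047298053	XP_051693453	IRAK1	interleukin-1 receptor-associated kinase 1	82.7	Unplaced
NP_004970	XP_002719951	KCND1	potassium voltage-gated channel subfamily D member 1	97.1	X
NP_000416	XP_051693407	L1CAM	neural cell adhesion molecule L1	91.3	Unplaced
NP_001116078	XP_008271376	LAMP2	lysosome-associated membrane glycoprotein 2	84.2	X
XP_016884927	XP_008271183	LPAR4	lysophosphatidic acid receptor 4	98.4	X
NP_001354845	XP_008271178	MAGT1	magnesium transporter protein 1	97.3	X
NP_689794	XP_051683552	MOSPD2	motile sperm domain-containing protein 2	88.0	X
XP_054182806	XP_051683121	NALF2	NALCN channel auxiliary factor 2	86.7	X
NP_000504	NP_001309193	OPN1MW	medium-wave-sensitive opsin 1	87.9	Unplaced
XP_005274486	XP_002724295	P2RY8	P2Y purinoceptor 8	78.9	Unplaced
XP_047297954	XP_008271184	P2RY10	putative P2Y receptor family member 10	87.9	X
NP_006658	XP_002720306	PGRMC1	membrane-associated progesterone receptor component 1	93.8	X
NP_000524	XP_008271259	PLP1	myelin proteolipid protein	99.6	X
NP_002659	NP_001075566	PLP2	proteolipid protein 2	88.2	X
XP_047298203	XP_008248506	PLXNA3	plexin-A3	88.5	Unplaced
NP_005384	XP_017194059	PLXNB3	plexin-B3	89.0	Unplaced
NP_001135867	XP_008270716	PRRG1	transmembrane gamma-carboxyglutamic acid protein 1	96.3	X
NP_006508	XP_051691041	SLC16A2	monocarboxylate transporter 8	96.8	Unplaced
XP_011529704	XP_008271409	SLC25A14	brain mitochondrial carrier protein 1	91.6	X
NP_001143	XP_002720308	SLC25A5	ADP/ATP translocase 2	98.3	X
XP_054184094	XP_051682846	SLC38A5	sodium-coupled neutral amino acid transporter 5	83.9	X
NP_009162	XP_002720288	SLC6A14	sodium- and chloride-dependent neutral and basic amino acid transporter B(0+)	90.8	X
NP_005620	NP_001075866	SLC6A8	sodium- and chloride-dependent creatine transporter 1	97.5	Unplaced
XP_047298533	XP_051687602	SLITRK2	SLIT and NTRK-like protein 2	98.3	Unplaced
XP_054182427	XP_008271667	SLITRK4	SLIT and NTRK-like protein 4	98.1	Unplaced
NP_001156408	XP_051691991	SMIM9	small integral membrane protein 9	69.7	Unplaced
XP_016885382	XP_051682971	SRPX	sushi repeat-containing protein SRPX, partial	94.6	X
XP_047298063	XP_008247483	STS	steryl-sulfatase	65.1	Unplaced
NP_003170	XP_051682874	SYP	synaptophysin	79.8	X
NP_004606	XP_017205349	TSPAN7	tetraspanin-7	99.2	X
XP_011529490	XP_002722247	VAMP7	vesicle-associated membrane protein 7	66.3	Unplaced
XP_005274644	XP_008271435	XG	glycoprotein Xg	47.8	X
XP_011529256	XP_002720425	XKRX	XK-related protein 2	91.2	X
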