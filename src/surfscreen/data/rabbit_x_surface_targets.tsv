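accession	gene_name	gene_source	protein_name	topology	go_classes	experimental
G1TEF4	ACE2	uniprot	Angiotensin-converting enzyme	SP+TM	CS,PM,ES	yes
G1SSU5	ADGRG2	uniprot	Adhesion G protein-coupled receptor G2	SP+TM	PM	yes
Q8MKE9	AGTR2	uniprot	Type-2 angiotensin II receptor	TM	PM	yes
G1SMQ1	AMOT	uniprot	Angiomotin	GLOB	CS,PM,ESPM	yes
G1T923	ATP6AP2	uniprot	Renin receptor	SP+TM	CS,PM,ESPM	yes
G1T6U3	ATP7A	uniprot	P-type Cu(+) transporter	TM	PM	yes
G1TUV0	BRS3	uniprot	Bombesin receptor subtype-3	TM	PM	yes
G1SNI0	CACNA1F	uniprot	Calcium voltage-gated channel subunit alpha1 F	TM	PM	yes
G1SV48	CD24	eggnog	CD24 molecule	SP	CS,PM,ESPM,ACPM,ACESPM	yes
G1SKP7	CD40LG	uniprot	CD40 ligand	TM	CS,PM,ESPM,ES	yes
Q9TTU3	CLCN5	uniprot	H(+)/Cl(-) exchange transporter 5	TM	PM	yes
G1TSU9	CLDN2	uniprot	Claudin 2	TM	PM	no
G1T4N6	CLTRN	uniprot	Collectrin, amino acid transport regulator	SP+TM	PM	yes
A0A5F9CEX7	CXCR3	uniprot	C-X-C chemokine receptor type 3	TM	CS,PM,ESPM	yes
A0A5F9CNI6	CYBB	uniprot	Cytochrome b-245 beta chain	TM	PM,ICPM	yes
G1TB31	CYSLTR1	uniprot	Cysteinyl leukotriene receptor 1	TM	PM,ICPM	yes
G1T9S6	EDA	uniprot	Ectodysplasin A	TM	PM,ES,ICPM	yes
A0A5F9D0L9	EDA2R	uniprot	Ectodysplasin A2 receptor	SP+TM	PM	no
A0A5F9CVB5	EFNB1	uniprot	Ephrin B1	SP+TM	PM	yes
G1TPG8	ENOX2	uniprot	Ecto-NOX disulfide-thiol exchanger 2	GLOB	CS,PM,ESPM	yes
A0A5F9CPD1	GDPD2	uniprot	Glycerophosphodiester phosphodiesterase domain containing 2	TM	PM	yes
G1TMB8	GJB1	uniprot	Gap junction protein	TM	PM	yes
G1T1J4	GLRA2	uniprot	Glycine receptor alpha 2	SP+TM	PM,ICPM	yes
G1T836	GLRA4	eggnog	Glycine receptor alpha 4	SP+TM	PM,ICPM	yes
A0A5F9DIT5	GPC4	uniprot	Glypican 4	TM	CS,PM,ESPM	yes
G1SN36	GPR174	uniprot	G protein-coupled receptor 174	TM	PM	no
G1SD16	GRIA3	uniprot	Glutamate receptor	SP+TM	PM,ICPM	yes
G1T4A8	GRPR	uniprot	Gastrin-releasing peptide receptor	TM	PM,ICPM	yes
G1SXP0	GUCY2F	uniprot	Guanylate cyclase	SP+TM	PM	yes
A0A5F9C5Z9	HEPH	uniprot	Hephaestin	SP+TM	PM	yes
A0A5F9DJ94	HNRNPM	eggnog	RRM domain-containing protein	GLOB	CS	yes
G1TAG7	HTR2C	uniprot	5-hydroxytryptamine receptor 2C	SP+TM	CS,PM,ESPM,ICPM	yes
G1TBS6	IL1RAPL1	uniprot	Interleukin-1 receptor accessory protein-like 1	SP+TM	CS,PM	yes
G1TPE7	IL2RG	eggnog	Cytokine receptor common subunit gamma	TM	CS,PM,ESPM	yes
G1SVL1	ITM2A	uniprot	Integral membrane protein 2	TM	PM	no
G1TSW5	KCNE5	uniprot	Potassium voltage-gated channel subfamily E regulatory subunit 5	TM	PM,ICPM	yes
U3KP42	MMGT1	eggnog	Membrane magnesium transporter	TM	PM	yes
G1SCP8	MSN	eggnog	Moesin	GLOB	CS,PM	yes
G1TU56	NDP	uniprot	Norrin cystine knot growth factor NDP	SP	CS,ES	yes
G1TYL9	NLGN3	uniprot	Neuroligin 3	SP+TM	CS,PM,ICPM	yes
G1SPD7	NOX1	uniprot	NADPH oxidase 1	TM	PM,ICPM	yes
G1T124	OR13H1	uniprot	Olfactory receptor family 13 subfamily H member 1	TM	PM	no
G1TCY0	P2RY4	uniprot	P2Y purinoceptor 4	TM	PM	yes
A0A5F9DQS9	PCDH11X	eggnog	Cadherin domain-containing protein	SP+TM	PM	no
G1TAD7	PCDH19	uniprot	Protocadherin 19	SP+TM	PM	no
G1SQ59	PHEX	uniprot	Phosphate-regulating endopeptidase homolog X-linked	TM	CS	yes
G1T949	PORCN	uniprot	Porcupine O-acyltransferase	TM	PM,ICPM	yes
G1T7A1	PTCHD1	uniprot	Patched domain-containing 1	TM	PM	yes
G1SZZ7	RS1	uniprot	Retinoschisin 1	SP	PM,ESPM,ES	no
G1SZJ1	SLC7A3	uniprot	Solute carrier family 7 member 3	TM	PM	yes
G1T4W3	SLC9A6	uniprot	Sodium/hydrogen exchanger	SP+TM	PM	yes
G1SLC9	SLC9A7	uniprot	Sodium/hydrogen exchanger	SP+TM	PM	no
G1T0T4	SRPX2	uniprot	Sushi repeat containing protein X-linked 2	SP	CS,PM,ES	yes
G1SN13	TENM1	uniprot	Teneurin transmembrane protein 1	TM	PM,ICPM	yes
O62852	TRPC5	uniprot	Short transient receptor potential channel 5	TM	PM	no
A0A5F9CK03	VSIG1	uniprot	V-set and immunoglobulin domain-containing protein 1	SP+TM	PM	yes
G1SR92	XK	uniprot	XK-related protein	TM	PM	no
A0A5F9CW02		none	Transmembrane protein 182	TM	PM	no
G1THX1		none	Sodium/hydrogen exchanger	TM	PM	no
G1TL60		none	Olfactory receptor	TM	PM	no
U3KP07		none	receptor protein-tyrosine kinase	TM	PM	no
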