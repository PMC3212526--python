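family	gene	mouse_homologue	nj	mp	ml	accession	annotation	flag
ASCa	GpAsh1	Mash1	99	92	99	XP_002915515.1	Hypothetical protein	
ASCa	GpAsh2	Mash2	92	91	97	XP_002920180.1	Ash2	
ASCb	GpAsh3a	Mash3a	98	99	90	XP_002916197.1	Ash3a	
ASCb	GpAsh3b	Mash3b	98	97	100	hmm367624.p	Hypothetical protein	
ASCb	GpAsh3c	Mash3c	99	97	71	hmm285394.p	Hypothetical protein	
MyoD	GpMyoD	MyoD	99	97	94	XP_002928807.1	MyoD	
MyoD	GpMyoG	MyoG	100	98	96	XP_002925479.1	MyoG	
MyoD	GpMyf5	Myf5	99	77	78	XP_002916822.1	Myf5	
MyoD	GpMyf6	Myf6	99	89	78	XP_002916823.1	Myf6	
E12/E47	GpTF12	TF12	82	n/m	n/m	XP_002920720.1	TF12	
E12/E47	GpE2A	E2A	100	97	98	XP_002923565.1	E2A	
E12/E47	GpKA1	KA1	65	87	57	Not available	/	
E12/E47	GpTCF4	TCF4	90	21	82	XP_002914713.1	TCF4	
Ngn	GpAth4a	Math4a	99	95	97	XP_002926036.1	Neurogenin-2-like	
Ngn	GpAth4b	Math4b	99	93	99	XP_002913770.1	Neurogenin-3-like	
Ngn	GpAth4c	Math4c	99	85	99	XP_002913012.1	Neurogenin-1-like	
NeuroD	GpNDF1	NDF1	89	27	80	XP_002922319.1	NDF1	
NeuroD	GpNDF2	NDF2	88	68	89	XP_002916875.1	NDF2	
NeuroD	GpAth2	Math2	93	77	89	XP_002919308.1	NDF6	
NeuroD	GpAth3	Math3	99	96	98	XP_002930692.1	NDF4	
Atonal	GpAth1	Math1	100	99	100	XP_002915330.1	Ath1	
Atonal	GpAth5	Math5	100	100	100	XP_002913786.1	Ath7	
Mist	GpMist1	Mist1	99	97	n/m	Not available	/	
Beta3	GpBeta3b	Beta3b	100	59	n/m	XP_002925784.1	Class E bHLH protein 23	whole_protein
Oligo	GpOligo1	Oligo1	91	85	98	XP_002919636.1	Oligo1	
Oligo	GpOligo2	Oligo2	88	59	56	XP_002919637.1	Oligo2	
Oligo	GpOligo3	Oligo3	90	73	98	XP_002915132.1	Oligo3	
Net	GpAth6	Math6	100	100	100	XP_002928677.1	Ath8	
Mesp	GpMesp1	Mesp1	99	78	n/m	XP_002919616.1	Mesp1	whole_protein
Mesp	GpPMeso1	pMeso1	100	100	97	XP_002915045.1	Mesogenin-1	
Twist	GpTwist	Twist	91	64	n/m	XP_002915415.1	Hypothetical protein	
Twist	GpDermo1	Dermo1	90	55	90	XP_002922521.1	Twist-2-like	
Paraxis	GpParaxis	Paraxis	78	70	86	XP_002925450.1	Transcription factor 15	
MyoRa	GpMyoR	MyoR	75	64	84	XP_002922844.1	Musculin	
MyoRa	GpPod1	Pod1	78	25	n/m	XP_002922333.1	Transcription factor 21	
MyoRb	GpMyoRb1	MyoRb1	100	100	100	XP_002916432.1	Hypothetical protein	
MyoRb	GpMyoRb2	MyoRb2	100	99	93	XP_002913861.1	Transcription factor 23	
Hand	GpDHand	dHand	100	64	n/m	XP_002912726.1	Hand 2	
Hand	GpEHand	eHand	99	99	99	XP_002917201.1	Hand 1	
PTFa	GpPTFa	PTFa	100	100	97	XP_002913208.1	Hypothetical protein	
PTFb	GpPTFb	PTFb	100	100	99	XP_002915418.1	Fer3	
SCL	GpTal1	Tal1	100	71	85	hmm534354.p	Hypothetical protein	
SCL	GpTal2	Tal2	99	94	88	XP_002927719.1	Tal2	
SCL	GpLyl1	Lyl1	99	99	100	XP_002921032.1	Lyl1	
NSCL	GpHen1	Hen1	100	100	89	XP_002928490.1	HLH protein-1-like	whole_protein
NSCL	GpHen2	Hen2	60	40	n/m	XP_002925359.1	HLH protein-2-like	
SRC	GpSRC1	SRC1	100	99	98	XP_002913840.1	NcoA 1	
SRC	GpSRC2	SRC2	100	100	99	XP_002918551.1	NcoA 2	
SRC	GpSRC3	SRC3	100	100	99	XP_002927046.1	NcoA 3	
FIGα	GpFiga	Figa	100	100	100	XP_002914962.1	Figa	
Myc	GpN-Myc	N-Myc	99	70	85	XP_002923116.1	N-Myc	
Myc	GpC-Myc	C-Myc	100	100	100	XP_002915028.1	C-Myc	
Myc	GpL-Myc	L-Myc	100	100	99	XP_002927604.1	L-Myc	
Mad	GpMxi1	Mxi1	100	99	96	XP_002930845.1	Mxi1	
Mad	GpMad1	Mad1	100	100	92	XP_002914951.1	Mad1	
Mad	GpMad3	Mad3	100	98	91	XP_002928184.1	Mad3	
Mad	GpMad4	Mad4	98	87	91	XP_002916603.1	Mad4	
Mnt	GpMnt	Mnt	100	100	99	XP_002918069.1	Mnt	
Max	GpMax	Max	100	100	100	XP_002914193.1	Max	
USF	GpUSF1	USF1	100	98	100	XP_002928795.1	USF1	
USF	GpUSF2	USF2	92	38	99	XP_002920933.1	USF2	
MITF	GpMITF	MITF	75	n/m	n/m	XP_002927657.1	MITF	
MITF	GpTFEb	TFEb	100	100	98	XP_002914561.1	TFEb	
MITF	GpTFEc	TFEc	98	97	96	XP_002923929.1	TFEc	
MITF	GpTFE3	TFE3	63	52	n/m	XP_002917800.1	TFE3	
SREBP	GpSREBP1	SREBP1	100	99	n/m	XP_002923179.1	SREBP1	
SREBP	GpSREBP2	SREBP2	100	100	100	XP_002929331.1	SREBP2	
AP4	GpAP4	AP4	100	100	99	XP_002924645.1	AP4	
MLX	GpMlx	Mlx	100	99	92	XP_002923532.1	WBSCR14	
MLX	GpMondoA	MondoA	100	100	97	XP_002913172.1	Mlx-interacting protein	
TF4	GpTF4	TF4	100	100	100	XP_002922185.1	Max-like protein X	
Clock	GpClk	Clk	100	95	100	XP_002919413.1	Clk	
Clock	GpNPAS2	NPAS2	100	99	100	XP_002919235.1	NPAS2	
ARNT	GpARNT1	ARNT1	97	61	n/m	XP_002919403.1	ARNT1	
ARNT	GpARNT2	ARNT2	96	87	97	XP_002919129.1	ARNT2	
Bmal	GpBmal1	Bmal1	100	99	97	XP_002926157.1	ARNT-like protein 1	
Bmal	GpBmal2	Bmal2	100	100	100	XP_002917162.1	ARNT-like protein 2	whole_protein
Sim	GpSim1	Sim1	97	74	96	XP_002922016.1	Sim1	
Sim	GpSim2	Sim2	97	83	90	hmm348774.p	Hypothetical protein	
AHR	GpAHR1	AHR1	100	99	100	XP_002917450.1	AHR1	
AHR	GpAHR2	AHR2	81	64	n/m	XP_002926684.1	AHRR	
Trh	GpNPAS3	NPAS3	100	91	82	hmm740504.p	Hypothetical protein	
HIF	GpHif1a	Hif1a	100	100	100	XP_002913080.1	Hif1a	
HIF	GpHif3a	Hif3a	100	100	100	XP_002923099.1	Hif3a	
HIF	GpNPAS1	NPAS1	100	100	95	XP_002923107.1	NPAS1	
HIF	GpEPAS1	EPAS1	100	99	100	XP_002912483.1	EPAS1	
Emc	GpId1	Id1	93	57	n/m	hmm387023.p	Hypothetical protein	
Emc	GpId2	Id2	87	82	56	XP_002923275.1	Id2	
Emc	GpId3	Id3	99	92	100	XP_002913316.1	Id3	
Emc	GpId4	Id4	100	90	76	hmm7844.p	Hypothetical protein	
Hey	GpHerp1	Herp1	96	86	96	XP_002927896.1	Herp1	
Hey	GpHerp2	Herp2	96	50	n/m	XP_002915182.1	Herp2	
Hey	GpHEYL	HEYL	98	94	98	XP_002930399.1	HEYL	
Hey	GpHey4	Hey4	100	100	92	XP_002914075.1	HELT-like protein	
H/E(spl)	GpDec1	Dec1	76	67	99	XP_002920034.1	Class E bHLH protein 40	
H/E(spl)	GpDec2	Dec2	73	n/m	n/m	hmm164814.p	Hypothetical protein	
H/E(spl)	GpHes1a	Hes1	99	66	84	XP_002930213.1	Hes4-like protein	
H/E(spl)	GpHes1b	Hes1	100	100	100	XP_002923794.1	Hes1	
H/E(spl)	GpHes2	Hes2	97	67	88	XP_002923913.1	Hes2	
H/E(spl)	GpHes3	Hes3	100	97	98	XP_002923915.1	Hes3	
H/E(spl)	GpHes7	Hes7	100	100	97	hmm475304.p	Hypothetical protein	
COE	GpEBF1	EBF1	95	45	58	XP_002912553.1	COE1	
COE	GpEBF2	EBF2	94	89	56	XP_002914472.1	COE2	
COE	GpEBF3	EBF3	72	n/m	n/m	XP_002922830.1	COE3	
Orphan	GpOrphan2	Orphan2	100	100	59	XP_002913251.1	MAX gene-associated	
Orphan	GpOrphan3	Orphan3	100	100	n/m	XP_002923506.1	Sohlh2-like protein	
Orphan	GpOrphan4	Orphan4	100	100	100	Not available	/	
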