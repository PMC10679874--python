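id	name	category	paralogue_group
SmB	SmB	Sm/LSm	
SmD1	SmD1	Sm/LSm	
SmD2	SmD2	Sm/LSm	
SmD3	SmD3	Sm/LSm	
SmE	SmE	Sm/LSm	
SmF	SmF	Sm/LSm	
SmG	SmG	Sm/LSm	
LSm2	LSm2	Sm/LSm	
LSm3	LSm3	Sm/LSm	
LSm4	LSm4	Sm/LSm	
LSm5	LSm5	Sm/LSm	
LSm6	LSm6	Sm/LSm	
LSm7	LSm7	Sm/LSm	
LSm8	LSm8	Sm/LSm	
U1-70K	U1-70K	U1	
U1A	U1A	U1	U1A-U2Bpp
U1C	U1C	U1	
Prp39	Prp39	U1	
Prp40	Prp40	U1	
Luc7L	Luc7L	U1	
Luc7L2	Luc7L2	U1	
Luc7L3	Luc7L3	U1	
S164	S164	U1	
SF3A1	SF3A1	U2-related	
SF3A2	SF3A2	U2-related	
SF3A3	SF3A3	U2-related	
SF3B1	SF3B1	U2-related	
SF3B2	SF3B2	U2-related	
SF3B3	SF3B3	U2-related	
SF3B4	SF3B4	U2-related	
SF3B5	SF3B5	U2-related	
SF3B6	SF3B6	U2-related	
PHF5A	PHF5A	U2-related	
U2A	U2A'	U2-related	
U2Bpp	U2B″	U2-related	U1A-U2Bpp
SF1	SF1	U2-related	SF1-set
U2AF65	U2AF65	U2-related	
U2AF35	U2AF35	U2-related	
PUF60	PUF60	U2-related	
SPF45	SPF45	U2-related	
SPF30	SPF30	U2-related	
CHERP	CHERP	U2-related	
SR140	SR140	U2-related	
Tat-SF1	Tat-SF1	U2-related	
Prp8	Prp8	U4/U5/U6	
Brr2	Brr2	U4/U5/U6	
Snu114	Snu114	U4/U5/U6	
Prp6	Prp6	U4/U5/U6	
Prp28	Prp28	U4/U5/U6	
SNRNP40	SNRNP40	U4/U5/U6	
Dib1	Dib1	U4/U5/U6	
Prp31	Prp31	U4/U5/U6	
Prp3	Prp3	U4/U5/U6	
Prp4	Prp4	U4/U5/U6	
CypH	CypH	U4/U5/U6	
15.5K	15.5K	U4/U5/U6	
Sad1	Sad1	U4/U5/U6	
Snu66	Snu66	U4/U5/U6	
snRNP27	snRNP27	U4/U5/U6	
Prp38	Prp38	U4/U5/U6	
Snu23	Snu23	U4/U5/U6	
MFAP1	MFAP1	U4/U5/U6	
RED	RED	U4/U5/U6	
Prp19	Prp19	NTC/NTR/IBC	
CDC5L	CDC5L	NTC/NTR/IBC	
PLRG1	PLRG1	NTC/NTR/IBC	
SPF27	SPF27	NTC/NTR/IBC	
CTNNBL1	CTNNBL1	NTC/NTR/IBC	
HSPA8	HSPA8	NTC/NTR/IBC	HSPA8-HSPA1A
HSPA1A	HSPA1A	NTC/NTR/IBC	HSPA8-HSPA1A
AD002	AD002	NTC/NTR/IBC	
NPW38	NPW38	NTC/NTR/IBC	
NPW38BP	NPW38BP	NTC/NTR/IBC	
Syf1	Syf1	NTC/NTR/IBC	
Syf2	Syf2	NTC/NTR/IBC	
Isy1	Isy1	NTC/NTR/IBC	
CCDC16	CCDC16	NTC/NTR/IBC	
Aquarius	Aquarius	NTC/NTR/IBC	
XAB2	XAB2	NTC/NTR/IBC	
PPIE	PPIE	NTC/NTR/IBC	
PRCC	PRCC	NTC/NTR/IBC	
RBM22	RBM22	NTC/NTR/IBC	
SNIP1	SNIP1	RES	
RBMX2	RBMX2	RES	
BUD13	BUD13	RES	
eIF4A3	eIF4A3	EJC/TREX	
MAGOH	MAGOH	EJC/TREX	
Y14	Y14	EJC/TREX	
MLN51	MLN51	EJC/TREX	
UAP56	UAP56	EJC/TREX	
Aly	Aly	EJC/TREX	
THOC1	THOC1	EJC/TREX	
THOC2	THOC2	EJC/TREX	
THOC3	THOC3	EJC/TREX	
THOC5	THOC5	EJC/TREX	
THOC6	THOC6	EJC/TREX	
THOC7	THOC7	EJC/TREX	
CIP29	CIP29	EJC/TREX	
Pinin	Pinin	EJC/TREX	
Acinus	Acinus	EJC/TREX	
Prp2	Prp2	ATPase	
Prp16	Prp16	ATPase	
Prp22	Prp22	ATPase	
Prp43	Prp43	ATPase	
DHX35	DHX35	ATPase	
DDX41	DDX41	ATPase	
DDX57	DDX57	ATPase	
CBP80	CBP80	CBC	
CBP20	CBP20	CBC	
Dbr1	Dbr1	LDE	
TCERG1	TCERG1	stage-specific:A	
THRAP3	THRAP3	stage-specific:A	
BCLAF1	BCLAF1	stage-specific:A	
RBM25	RBM25	stage-specific:A	
RBM15	RBM15	stage-specific:A	
SUGP1	SUGP1	stage-specific:A	
DDX42	DDX42	stage-specific:A	
DDX46	DDX46	stage-specific:A	
ZRSR2	ZRSR2	stage-specific:A	
PRPF38B	PRPF38B	stage-specific:A	
ZCCHC10	ZCCHC10	stage-specific:A	
WTAP	WTAP	stage-specific:A	
SON	SON	stage-specific:A	
SREK1	SREK1	stage-specific:A	
FUBP3	FUBP3	stage-specific:A	
TSSC4	TSSC4	stage-specific:pre-B	
Smu1	Smu1	stage-specific:B	
FBP21	FBP21	stage-specific:B	
UBL5	UBL5	stage-specific:B	
CD2BP2	CD2BP2	stage-specific:B	
SNRNP48	SNRNP48	stage-specific:B	
SNRNP25	SNRNP25	stage-specific:B	
TXNL4B	TXNL4B	stage-specific:B	
ZMAT2	ZMAT2	stage-specific:B	
CCDC94	CCDC94	stage-specific:B	
GPATCH1	GPATCH1	stage-specific:B	
USP39	USP39	stage-specific:B	
RBM42	RBM42	stage-specific:pre-Bact	
NY-CO-10	NY-CO-10	stage-specific:Bact	
PPIL2	PPIL2	stage-specific:Bact	
PPIL3	PPIL3	stage-specific:Bact	
PPIL4	PPIL4	stage-specific:Bact	
GPKOW	GPKOW	stage-specific:Bact	
RNF113A	RNF113A	stage-specific:Bact	
NKAP	NKAP	stage-specific:Bact	
CWC22	CWC22	stage-specific:B*/C	
CCDC130	CCDC130	stage-specific:B*/C	
CCDC49	CCDC49	stage-specific:B*/C	
CCDC12	CCDC12	stage-specific:B*/C	
SLU7	SLU7	stage-specific:B*/C	
Prp18	Prp18	stage-specific:B*/C	
Prp17	Prp17	stage-specific:B*/C	
FAM32A	FAM32A	stage-specific:B*/C	
CACTIN	CACTIN	stage-specific:B*/C	
SDE2	SDE2	stage-specific:B*/C	
FRA10AC1	FRA10AC1	stage-specific:B*/C	
C9orf78	C9orf78	stage-specific:B*/C	
PPWD1	PPWD1	stage-specific:B*/C	
WDR83	WDR83	stage-specific:B*/C	
ZNF830	ZNF830	stage-specific:B*/C	
ESS2	ESS2	stage-specific:B*/C	
PRKRIP1	PRKRIP1	stage-specific:B*/C	
LENG1	LENG1	stage-specific:B*/C	
DGCR14	DGCR14	stage-specific:B*/C	
FAM50A	FAM50A	stage-specific:pre-C*	FAM50A-FAM50B
PPIL1	PPIL1	stage-specific:C*/P	
ERH	ERH	stage-specific:C*/P	
C1QBP	C1QBP	stage-specific:C*/P	
DNAJC8	DNAJC8	stage-specific:C*/P	
ZC3H18	ZC3H18	stage-specific:C*/P	
SERBP1	SERBP1	stage-specific:C*/P	
GPATCH2	GPATCH2	stage-specific:C*/P	
NRDE2	NRDE2	stage-specific:C*/P	
MORG1	MORG1	stage-specific:C*/P	
E1B-AP5	E1B-AP5	stage-specific:C/C*-misc	
PABP1	PABP1	stage-specific:C/C*-misc	
DDX3	DDX3	stage-specific:C/C*-misc	
PPP1CA	PPP1CA	stage-specific:C/C*-misc	
PPP2CA	PPP2CA	stage-specific:C/C*-misc	
PPIG	PPIG	stage-specific:C/C*-misc	
SRRM1	SRRM1	stage-specific:C/C*-misc	
SRRM2	SRRM2	stage-specific:C/C*-misc	
NOSIP	NOSIP	stage-specific:C/C*-misc	
AKAP17A	AKAP17A	stage-specific:C/C*-misc	
PPIL6	PPIL6	stage-specific:C/C*-misc	
GPATCH3	GPATCH3	stage-specific:C/C*-misc	
WDR70	WDR70	stage-specific:C/C*-misc	
TFIP11	TFIP11	stage-specific:ILS	
GCFC2	GCFC2	stage-specific:ILS	
SRSF1	SRSF1	SR	
SRSF2	SRSF2	SR	
SRSF3	SRSF3	SR	
SRSF4	SRSF4	SR	
SRSF5	SRSF5	SR	
SRSF6	SRSF6	SR	
SRSF7	SRSF7	SR	
SRSF9	SRSF9	SR	
SRSF10	SRSF10	SR	
SRSF11	SRSF11	SR	
Tra2A	Tra2A	SR	
Tra2B	Tra2B	SR	
hnRNP_A0	hnRNP A0	hnRNP	hnRNP-A-set
hnRNP_A1	hnRNP A1	hnRNP	hnRNP-A-set
hnRNP_A3	hnRNP A3	hnRNP	hnRNP-A-set
hnRNP_A2-B1	hnRNP A2/B1	hnRNP	hnRNP-A-set
hnRNP_AB	hnRNP AB	hnRNP	
hnRNP_C	hnRNP C	hnRNP	
hnRNP_D	hnRNP D	hnRNP	
hnRNP_DL	hnRNP DL	hnRNP	
hnRNP_E1	hnRNP E1	hnRNP	
hnRNP_E2	hnRNP E2	hnRNP	
hnRNP_F	hnRNP F	hnRNP	
hnRNP_G	hnRNP G	hnRNP	
hnRNP_H	hnRNP H	hnRNP	
hnRNP_H2	hnRNP H2	hnRNP	
hnRNP_K	hnRNP K	hnRNP	
hnRNP_L	hnRNP L	hnRNP	
hnRNP_M	hnRNP M	hnRNP	
hnRNP_Q	hnRNP Q	hnRNP	
hnRNP_R	hnRNP R	hnRNP	
hnRNP_U	hnRNP U	hnRNP	
hnRNP_UL1	hnRNP UL1	hnRNP	
hnRNP_UL2	hnRNP UL2	hnRNP	
RALY	RALY	hnRNP	
Quaking	Quaking	pre-mRNA-binding	SF1-set
Sam68	Sam68	pre-mRNA-binding	SF1-set
Sam-2	Sam-2	pre-mRNA-binding	SF1-set
PTBP1	PTBP1	pre-mRNA-binding	PTBP1-PTBP2
PTBP2	PTBP2	pre-mRNA-binding	PTBP1-PTBP2
TIA1	TIA1	pre-mRNA-binding	
TIAR	TIAR	pre-mRNA-binding	
ELAV1	ELAV1	pre-mRNA-binding	
SRPK1	SRPK1	miscellaneous	SRPK1-SRPK2
SRPK2	SRPK2	miscellaneous	SRPK1-SRPK2
p68	p68	miscellaneous	p68-p72
p72	p72	miscellaneous	p68-p72
CCAR1	CCAR1	miscellaneous	CCAR1-CCAR2
CCAR2	CCAR2	miscellaneous	CCAR1-CCAR2
RBM5	RBM5	miscellaneous	RBM5-RBM10
RBM10	RBM10	miscellaneous	RBM5-RBM10
RBM23	RBM23	miscellaneous	RBM23-RBM39
RBM39	RBM39	miscellaneous	RBM23-RBM39
FAM50B	FAM50B	miscellaneous	FAM50A-FAM50B
CIR1	CIR1	miscellaneous	CIR1-RP9
RP9	RP9	miscellaneous	CIR1-RP9
PRPF4B	PRPF4B	miscellaneous	
CLK1	CLK1	miscellaneous	
CDK11	CDK11	miscellaneous	
CELF1	CELF1	miscellaneous	
RBFOX2	RBFOX2	miscellaneous	
CDC2L2	CDC2L2	miscellaneous	
TOE1	TOE1	miscellaneous	
SNRK	SNRK	miscellaneous	
ZNF207	ZNF207	miscellaneous	
SUGP2	SUGP2	miscellaneous	
NCBP3	NCBP3	miscellaneous	
PPIL5	PPIL5	miscellaneous	
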