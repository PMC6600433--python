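gene	compartment	cell_type	invivo_time	direction	function
CAND1	lung	SAEC	1mo	down	Ubiquitin ligase regulation
CYCS	lung	SAEC	1mo	down	Electron transport chain in mitochondria
DENND5B	lung	SAEC	1mo	down	Calcium ion transmembrane transport
HS3ST3B1	lung	SAEC	1mo	down	Sulfotransferase
MAML1	lung	SAEC	1mo	down	Cell fate determination
MAN2B2	lung	SAEC	1mo	down	Hydrolase
METTL21	lung	SAEC	1mo	down	Methyltransferase
PIGS	lung	SAEC	1mo	down	GPI-anchor biosynthesis
PPP1C	lung	SAEC	1mo	down	Phosphatase
S100A5	lung	SAEC	1mo	up	Calcium binding
SEL1L	lung	SAEC	1mo	down	Misfolded protein translocation
SH3BP2	lung	SAEC	1mo	down	Adaptor protein
SLC7A1	lung	SAEC	1mo	down	Transmembrane transporter
TGM2	lung	SAEC	1mo	down	Transglutaminase
XRN2	lung	SAEC	1mo	down	Exonuclease
KIF14	lung	SAEC	6mo	down	Microtubule motor protein
MYBPC2	lung	SAEC	6mo	up	Myosin binding
PSD4	lung	SAEC	6mo	up	ARF protein signal transduction
TTLL7	lung	SAEC	6mo	down	Cell differentiation
ADH5	lung	SAEC	12mo	down	Alcohol dehydrogenase
ANLN	lung	SAEC	12mo	down	Cell growth and migration
ARF1	lung	SAEC	12mo	down	Guanine nucleotide binding
CCDC115	lung	SAEC	12mo	down	Unfolded protein binding
CYCS	lung	SAEC	12mo	down	Electron transport chain in mitochondria
DDX24	lung	SAEC	12mo	down	RNA helicase
FAM188A	lung	SAEC	12mo	down	Apoptosis
IKZF2	lung	SAEC	12mo	down	Zinc finger protein
IL1R1	lung	SAEC	12mo	down	Interleukin receptor
INTS4	lung	SAEC	12mo	down	snRNA processing
MAD2L1	lung	SAEC	12mo	down	Mitotic spindle assembly checkpoint
PIGU	lung	SAEC	12mo	down	Cell division control
PIKFYVE	lung	SAEC	12mo	down	Cytoskeletal functions, membrane trafficking, and receptor signaling
PNRC2	lung	SAEC	12mo	down	DNA/mRNA binding
PRKRIR	lung	SAEC	12mo	down	Regulation of cell proliferation
PRIM2	lung	SAEC	12mo	down	Replication of DNA
RNF19A	lung	SAEC	12mo	down	Ubiquitin ligase
SDHD	lung	SAEC	12mo	down	Succinate oxidation
SGOL2	lung	SAEC	12mo	down	Cell cycle regulation
SLC30A7	lung	SAEC	12mo	down	Zinc transporter
TMPO	lung	SAEC	12mo	down	Nuclear organization
TMPRSS6	lung	SAEC	12mo	up	Serine proteinase
UBE2E1	lung	SAEC	12mo	down	Ubiquitination
VAC14	lung	SAEC	12mo	down	Regulates levels of phosphatidylinositol 3,5-bisphosphate
WDR74	lung	SAEC	12mo	down	RNA regulation
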