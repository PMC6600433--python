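gene	compartment	cell_type	invivo_time	direction	function
CAND1	lung	HMVEC	1mo	down	Ubiquitin ligase regulation
HIST1H3F	lung	HMVEC	1mo	up	DNA structure
PPP1CC	lung	HMVEC	1mo	down	Phosphatase
SH2D1A	lung	HMVEC	1mo	down	T and B cell stimulation
SH3BP2	lung	HMVEC	1mo	down	Adaptor protein
SLC22A5	lung	HMVEC	1mo	down	Glucose transporter
TGM2	lung	HMVEC	1mo	down	Transglutaminase
HIST1H2AL	lung	HMVEC	6mo	up	DNA structure
TFEC	lung	HMVEC	6mo	down	Transcription factor
ABCE1	lung	HMVEC	12mo	down	Molecular transport
EIF4B	lung	HMVEC	12mo	down	Helicase
IKZF2	lung	HMVEC	12mo	down	Transcription factor
IL1R1	lung	HMVEC	12mo	down	Interleukin receptor
LXN	lung	HMVEC	12mo	down	Metallocarboxypeptidase inhibition
MID1	lung	HMVEC	12mo	up	Adaptor protein
NPM1	lung	HMVEC	12mo	down	ARF/p53 regulation
NUDT8	lung	HMVEC	12mo	up	Hydrolase
PIKFYVE	lung	HMVEC	12mo	down	Cytoskeletal functions, membrane trafficking, and receptor signaling
PPP1CC	lung	HMVEC	12mo	down	Phosphatase
SDHD	lung	HMVEC	12mo	down	Succinate oxidation
SLC30A7	lung	HMVEC	12mo	down	Zinc transporter
SMARCAD1	lung	HMVEC	12mo	down	Helicase
UBE2E1	lung	HMVEC	12mo	down	Ubiquitination
ZC3H13	lung	HMVEC	12mo	down	mRNA methylation
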