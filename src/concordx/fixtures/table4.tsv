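gene	compartment	cell_type	invivo_time	direction	function
PER1	blood	HMVEC	1mo	down	Circadian rhythm
SLC22A5	blood	HMVEC	1mo	down	Glucose transporter
TUBA1B	blood	HMVEC	1mo	up	Cell division
HIST1H3H	blood	HMVEC	6mo	up	Chromosomal structure
KPRP	blood	HMVEC	6mo	up	Keratinocyte differentiation
KRT79	blood	HMVEC	6mo	up	Epithelial cell integrity
MID1	blood	HMVEC	6mo	down	Adaptor protein
SHCBP1	blood	HMVEC	6mo	up	Cell proliferation
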