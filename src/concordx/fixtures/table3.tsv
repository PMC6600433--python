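gene	compartment	cell_type	invivo_time	direction	function
CFTR	blood	SAEC	1mo	down	Multidrug resistance
HSD17B2	blood	SAEC	1mo	up	Bone development
PER1	blood	SAEC	1mo	down	Circadian rhythm
RIMKLB	blood	SAEC	1mo	down	Amino acid synthesis
SH3RF3	blood	SAEC	1mo	down	Metal ion binding
SLC7A1	blood	SAEC	1mo	down	Amino acid transport
HMGB2	blood	SAEC	6mo	down	DNA bending
SYTL3	blood	SAEC	12mo	down	Vesicle trafficking
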