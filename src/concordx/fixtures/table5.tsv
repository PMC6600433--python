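gene	compartment	cell_type	invivo_time	direction
miR-183	lung	SAEC	1mo	up
miR-204	lung	SAEC	6mo	up
miR-335	lung	SAEC	12mo	up
miR-204	lung	HMVEC	6mo	up
miR-335	lung	HMVEC	12mo	up
miR-26b	lung	HMVEC	12mo	up
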