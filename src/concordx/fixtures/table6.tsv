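gene	compartment	cell_type	invivo_time	direction
miR-148b	blood	SAEC	1mo	up
miR-29c	blood	HMVEC	1mo	up
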