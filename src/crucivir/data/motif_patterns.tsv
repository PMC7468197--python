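#motif	regex	region	note
motif_I	FT[LI]NN	nterm	CRESS endonuclease motif I consensus; editable
motif_II	H[A-Z][HQ]	nterm	HUH metal-binding motif and its HUQ/HYQ variants
motif_III	Y[A-Z]{2,3}K	nterm	catalytic Tyr context
walker_A	G[A-Z]{4}GK[TS]	cterm	P-loop NTPase Walker A
walker_B	[ILMFV]{2}D[DE]	cterm	Walker B with hydrophobic leader
motif_C	[ILMFV][A-Z]TSN	cterm	SF3 helicase motif C
arg_finger	R	after_motif_C	any Arg within the window downstream of motif C
grs	[FWY][A-Z]{2}RL[A-Z]{2}F	nterm	geminivirus Rep sequence; low-confidence default
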