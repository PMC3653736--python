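# rnrscape packaged motif patterns, version 1.
# Illustrative amino-acid regular expressions for intervening-sequence
# screening (homing endonuclease and intein signatures). These are synthetic
# stand-in patterns shipped with the package, not a curated motif database.
# name	pattern
HNH_HEG	HNH.{10,40}[HN]
GIY_YIG	GIY.{8,13}YIG
LAGLIDADG	LAGL[IV]DADG
INTEIN_NTERM	C[LIVMF][STA]G[DE]T[LIVMF]
INTEIN_CTERM	[VIL]H[NG]C[LIVMF]AG
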