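# informal contraction <TAB> space-separated split
# Rule table applied during tokenization; matching is on the lowercased token.
gonna	gon na
wanna	wan na
gotta	got ta
lemme	lem me
gimme	gim me
dunno	dun no
kinda	kind a
sorta	sort a
outta	out ta
lotta	lot a
cannot	can not
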