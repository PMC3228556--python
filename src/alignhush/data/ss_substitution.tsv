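# default 3-state substitution table v1; synthetic approximation estimated from the package's SS-conserving alignment generator (seed 42, 500 pairs, pseudocount 1.0)
	H	E	C
H	1.005899	-2.762434	-2.756660
E	-2.762434	1.592653	-2.496737
C	-2.756660	-2.496737	1.831676
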