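trigger	count	kind
but	3	pseudo_negation
all family	2	pseudo_negation
her husband	1	family_experiencer
Discussed	1	pseudo_negation
However	1	pseudo_negation
is still	1	pseudo_negation
still has	1	pseudo_negation
But	1	pseudo_negation
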