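# Design iteration 1: single-mutant scan at the focus site (1015).
# Polar or positively charged identities plus the native Arg.
A 1015 PIKAA CHKNQRSTY
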