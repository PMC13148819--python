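# Design iteration 3: triple mutants combining favorable second-site
# substitutions with the fixed R1015H background.  Each promising site
# samples only its previously favorable identities or the native one.
A 37   PIKAA KR
A 782  PIKAA EK
A 787  PIKAA TMFW
A 803  PIKAA NKW
A 822  PIKAA KR
A 882  PIKAA YR
A 968  PIKAA NKR
A 1015 PIKAA H
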