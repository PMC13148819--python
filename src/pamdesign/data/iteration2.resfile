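# Design iteration 2: double mutants on a fixed R1015H background.
# The focus site is constrained to His; every other mutable site of the
# toy complex samples all twenty identities.
A 1015 PIKAA H
A 37   PIKAA ACDEFGHIKLMNPQRSTVWY
A 782  PIKAA ACDEFGHIKLMNPQRSTVWY
A 787  PIKAA ACDEFGHIKLMNPQRSTVWY
A 803  PIKAA ACDEFGHIKLMNPQRSTVWY
A 822  PIKAA ACDEFGHIKLMNPQRSTVWY
A 882  PIKAA ACDEFGHIKLMNPQRSTVWY
A 968  PIKAA ACDEFGHIKLMNPQRSTVWY
A 993  PIKAA ACDEFGHIKLMNPQRSTVWY
A 1019 PIKAA ACDEFGHIKLMNPQRSTVWY
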