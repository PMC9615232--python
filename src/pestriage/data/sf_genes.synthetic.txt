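# synthetic stand-in for the ACMG recommended secondary-findings gene list (v2.0)
RB1
BRCA2
LDLR
MYH7
KCNQ1
APC
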