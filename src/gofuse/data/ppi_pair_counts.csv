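# Published CAFA5 analysis: protein pairs with >=70% shared positive
# predicted GO terms among high-precision predictions, and how many of
# them carry an interaction-confidence score >= 70 in a local copy of the
# STRING score table, per aspect.
aspect,selected,matched
BP,179,141
MF,216,153
CC,183,109
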