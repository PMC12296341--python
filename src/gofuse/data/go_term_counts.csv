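# Published CAFA5 label-space statistics: GO terms per aspect before
# pruning (total) and the number removed by the default frequency
# threshold of 21 annotations (pruned).
aspect,total,pruned
BP,21285,13641
MF,7224,5740
CC,2957,1932
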