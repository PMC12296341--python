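# Published CAFA5 benchmark summary: protein-centric Fmax (%) of six base
# protein language models under linear probing (base) and with the full
# multi-modal fusion pipeline on top (enhanced), per GO aspect.
model,aspect,base,enhanced
Ankh,BP,17.44,42.10
Ankh,MF,50.56,67.56
Ankh,CC,59.68,68.99
ESM150M,BP,20.86,47.51
ESM150M,MF,55.81,71.84
ESM150M,CC,61.15,73.04
ESM650M,BP,24.10,49.76
ESM650M,MF,60.27,73.09
ESM650M,CC,62.87,73.92
ESM3B,BP,28.70,48.71
ESM3B,MF,63.80,72.86
ESM3B,CC,66.24,74.51
ESM15B,BP,33.57,50.78
ESM15B,MF,65.91,73.63
ESM15B,CC,67.12,74.67
PGLM,BP,34.32,55.08
PGLM,MF,69.90,78.81
PGLM,CC,70.39,79.65
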