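# Published CAFA5 benchmark summary: example-based F1 (%) of six base
# protein language models under linear probing (base) and with the full
# multi-modal fusion pipeline on top (enhanced), per GO aspect.
model,aspect,base,enhanced
Ankh,BP,16.34,29.62
Ankh,MF,36.45,48.92
Ankh,CC,39.97,50.37
ESM150M,BP,19.91,34.46
ESM150M,MF,40.41,53.80
ESM150M,CC,41.12,56.36
ESM650M,BP,21.72,37.31
ESM650M,MF,43.06,56.22
ESM650M,CC,43.15,59.31
ESM3B,BP,25.67,38.01
ESM3B,MF,46.23,57.03
ESM3B,CC,46.14,60.04
ESM15B,BP,29.11,38.47
ESM15B,MF,47.57,57.41
ESM15B,CC,49.51,59.73
PGLM,BP,30.95,39.25
PGLM,MF,47.99,57.32
PGLM,CC,51.56,60.29
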