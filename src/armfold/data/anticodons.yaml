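# Allowed anticodons per tRNA identity (gene sense strand, DNA alphabet),
# derived from standard invertebrate mitochondrial decoding rules. Where two
# anticodons are in common use across invertebrate mitogenomes both are
# allowed.
version: 1
anticodons:
  trnA: [TGC]
  trnC: [GCA]
  trnD: [GTC]
  trnE: [TTC]
  trnF: [GAA]
  trnG: [TCC]
  trnH: [GTG]
  trnI: [GAT]
  trnK: [CTT, TTT]
  trnL1: [TAG]
  trnL2: [TAA]
  trnM: [CAT]
  trnN: [GTT]
  trnP: [TGG]
  trnQ: [TTG]
  trnR: [TCG, ACG]
  trnS1: [GCT, TCT]
  trnS2: [TGA]
  trnT: [TGT]
  trnV: [TAC]
  trnW: [TCA]
  trnY: [GTA]
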