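# Gene-name normalization table, v1.
# Keys are matched case-insensitively after stripping spaces, hyphens,
# underscores and parenthesised codon qualifiers such as "(uur)".
version: 1
synonyms:
  co1: cox1
  coi: cox1
  cox1: cox1
  coxi: cox1
  co2: cox2
  coii: cox2
  cox2: cox2
  coxii: cox2
  co3: cox3
  coiii: cox3
  cox3: cox3
  coxiii: cox3
  cytb: cob
  cob: cob
  cb: cob
  atp6: atp6
  atpase6: atp6
  atp8: atp8
  atpase8: atp8
  nd1: nad1
  nad1: nad1
  nd2: nad2
  nad2: nad2
  nd3: nad3
  nad3: nad3
  nd4: nad4
  nad4: nad4
  nd4l: nad4L
  nad4l: nad4L
  nd5: nad5
  nad5: nad5
  nd6: nad6
  nad6: nad6
  rrnl: rrnL
  lrrna: rrnL
  16s: rrnL
  rrn16: rrnL
  l-rrna: rrnL
  rrns: rrnS
  srrna: rrnS
  12s: rrnS
  rrn12: rrnS
  s-rrna: rrnS
  dloop: CR
  d-loop: CR
  controlregion: CR
  cr: CR
  cr2: CR2
  trna: trnA
  trnc: trnC
  trnd: trnD
  trne: trnE
  trnf: trnF
  trng: trnG
  trnh: trnH
  trni: trnI
  trnk: trnK
  trnl1: trnL1
  trnl2: trnL2
  trnm: trnM
  trnn: trnN
  trnp: trnP
  trnq: trnQ
  trnr: trnR
  trns1: trnS1
  trns2: trnS2
  trnt: trnT
  trnv: trnV
  trnw: trnW
  trny: trnY
# Codon-qualified tRNA names map through the qualifier, not the bare letter.
codon_qualified:
  trnl(uur): trnL2
  trnl(taa): trnL2
  trnl(uaa): trnL2
  trnl(cun): trnL1
  trnl(tag): trnL1
  trnl(uag): trnL1
  trns(agn): trnS1
  trns(gct): trnS1
  trns(agy): trnS1
  trns(ucn): trnS2
  trns(tga): trnS2
  trns(uga): trnS2
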