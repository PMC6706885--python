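# Reference mitochondrial gene orders (37 genes; signed circular
# permutations, "-" = minus strand). One order per line, "name: genes".
# Control regions are not part of the gene orders; for the dysderoidea
# order the main control region lies between trnQ and trnM and the short
# second non-coding region between trnL2 and trnN.
pancrustacea: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
mesothelae: cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL2,-trnL1,-rrnL,-trnV,-rrnS,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
araneomorphae: cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,-trnL2,trnN,trnA,trnS1,trnR,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,trnI,-trnQ,trnM,nad2,trnW,-trnY,-trnC
mygalomorphae: cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,-trnL2,trnN,trnA,trnS1,trnR,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnI,-trnQ,trnM,nad2,trnW,-trnY,-trnC
dysderoidea: cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,-trnL2,trnN,trnA,trnS1,trnR,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnQ,trnM,trnI,nad2,trnW,-trnY,-trnC
entelegynae: cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,-trnL2,trnN,trnA,trnS1,trnR,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnQ,trnM,nad2,trnI,trnW,-trnY,-trnC
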