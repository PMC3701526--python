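delphacid	trnI,-trnQ,trnM,nad2,-trnC,trnW,-trnY,cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,nad6,-trnP,trnT,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS
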