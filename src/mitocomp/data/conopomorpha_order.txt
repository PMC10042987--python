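# Litchi fruit borer variant: trnA/trnR swapped within the trnA-trnF cluster
# (R-A-N-S1-E-F); AT-repeat insertions are planted separately by the preset.
trnM,trnI,-trnQ,ND2,trnW,-trnC,-trnY,COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnR,trnA,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,CYTB,trnS2,-ND1,-trnL1,-rrnL,-trnV,-rrnS,D-loop
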