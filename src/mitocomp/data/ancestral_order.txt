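# Lepidopteran mitogenome gene order (ancestral-for-moths MIQ arrangement),
# one genome per line: comma-separated signed labels, minus = minority (N) strand.
trnM,trnI,-trnQ,ND2,trnW,-trnC,-trnY,COI,trnL2,COII,trnK,trnD,ATP8,ATP6,COIII,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,CYTB,trnS2,-ND1,-trnL1,-rrnL,-trnV,-rrnS,D-loop
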