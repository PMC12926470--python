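source	target
Ccl5	Ccr5
Xcl1	Xcr1
Cd40lg	Cd40
Sell	Selplg
Il17a	Il17ra
Icosl	Icos
Tgfb1	Tgfbr1_Tgfbr2
Cd80	Cd28
Cd80	Ctla4
Cd69	Lgals1
Il2ra	Ptprc
Gzmb	Prf1
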