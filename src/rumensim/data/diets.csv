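exptr,group,fg,sg,wr,ac,pr,bu,la,k_fg_he,k_sg_he,k_pg_ps
O,no3-fit,329,207,49,10,2,2,20,0.036,0.100,0.044
VZ,no3-fit,245,252,76,6,1,1,11,0.029,0.094,0.055
VM,no3-fit,294,230,90,13,2,2,26,0.025,0.100,0.054
Hn1,3nop-fit,281,250,140,0,0,0,0,0.056,0.091,0.067
Hv,3nop-fit,198,244,157,3,0,0,5,0.043,0.087,0.070
Hn2,3nop-fit,322,230,118,0,0,0,0,0.049,0.085,0.071
Ls,3nop-fit,193,257,151,3,0,0,5,0.045,0.087,0.065
VW,3nop-fit,315,149,116,6,1,1,12,0.042,0.081,0.053
VL,evaluation,287,159,125,11,2,2,21,0.043,0.078,0.054
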