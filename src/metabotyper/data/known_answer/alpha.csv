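sample_id,role,injection_order,A1,A2,A3,IS_alpha
S01,study,2,100,200,10,50
S02,study,3,110,210,,50
S03,study,4,120,220,14,50
S04,study,5,300,400,30,50
S05,study,6,310,410,32,50
S06,study,7,320,420,31,50
QC1,qc,1,200,300,20,50
QC2,qc,8,205,310,21,50
QC3,qc,9,195,305,19,50
B1,blank,10,1,1,0,50
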