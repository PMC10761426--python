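sample_id,role,injection_order,X1,X2,X3,X4,IS_beta
S01,study,3,1000,50,700,80,100
S02,study,4,1100,55,720,NA,100
S03,study,5,1050,52,710,82,100
S04,study,6,2000,90,1400,160,100
S05,study,7,2100,95,1450,165,100
S07,study,8,2050,92,1420,162,100
QC1,qc,1,1500,70,1000,120,100
QC2,qc,2,1550,72,1050,125,100
QC3,qc,9,1450,69,980,118,100
B1,blank,10,2,1,1,1,100
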