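sample_id,genetic_group,age_years,bmi_sds,tanner_stage
S01,variant,10.5,4.1,I
S02,no_variant,12.0,3.8,II
S03,variant,9.8,5.0,I
S04,no_variant,11.2,4.6,III
S05,variant,13.1,3.2,IV
S06,no_variant,10.0,4.9,II
S07,variant,8.7,6.1,I
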