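group,mean_pct,sd_pct,n,ci_low_pct,ci_high_pct,p_value,flag,note
control,100,0,5,100,100,,,
lipus_treated,119.57,3.85,5,116.6,122.07,4.73e-08,**,printed interval inconsistent with t-formula at printed n
lipus_treated_ga_bpnn,124.93,1.28,5,123.34,126.52,8.65e-11,**,
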