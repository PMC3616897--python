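method,analyte,mean_pct,sd_pct,rsd_pct,consistent,comment
spectrophotometric,AML,100.18,1.620,1.617,yes,
spectrophotometric,OLM,99.24,2.312,2.33,no,printed mean/SD do not follow from the printed replicate recoveries
spectrophotometric,HCT,101.89,0.595,0.584,no,printed mean/SD do not follow from the printed replicate recoveries
ann,AML,101.11,0.895,0.885,yes,
ann,OLM,99.84,1.660,1.663,yes,
ann,HCT,100.90,1.035,1.026,yes,
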