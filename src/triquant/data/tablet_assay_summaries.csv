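method,analyte,mean_pct,sd_pct,rsd_pct,n,variance,consistent,comment
spectrophotometric,AML,98.28,0.552,0.562,6,0.305,yes,
spectrophotometric,OLM,98.31,0.829,0.843,6,0.687,yes,
spectrophotometric,HCT,97.12,0.587,0.604,6,0.345,no,printed mean/SD/variance do not follow from the printed replicate recoveries
ann,AML,99.37,1.321,1.329,6,1.745,yes,
ann,OLM,97.39,1.061,1.089,6,1.126,yes,
ann,HCT,97.44,1.144,1.174,6,1.309,yes,
reference,AML,98.56,0.615,0.624,6,0.378,yes,
reference,OLM,97.45,0.678,0.696,6,0.46,yes,
reference,HCT,97.50,0.736,0.755,6,0.542,yes,
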