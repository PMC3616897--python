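aml_ug_per_ml,olm_ug_per_ml,hct_ug_per_ml,method,analyte,recovery_pct
7,25,10,spectrophotometric,AML,101.56
5,15,13.75,spectrophotometric,AML,98.55
6,15,10,spectrophotometric,AML,97.27
7,15,11.25,spectrophotometric,AML,98.96
7,17.5,12.5,spectrophotometric,AML,101.56
5,17.5,10,spectrophotometric,AML,102.18
6,17.5,15,spectrophotometric,AML,100.30
5,20,12.5,spectrophotometric,AML,100.36
6,20,13.75,spectrophotometric,AML,100.91
7,25,10,spectrophotometric,OLM,101
5,15,13.75,spectrophotometric,OLM,100.36
6,15,10,spectrophotometric,OLM,98
7,15,11.25,spectrophotometric,OLM,100.2
7,17.5,12.5,spectrophotometric,OLM,102.26
5,17.5,10,spectrophotometric,OLM,100.52
6,17.5,15,spectrophotometric,OLM,100.66
5,20,12.5,spectrophotometric,OLM,97.71
6,20,13.75,spectrophotometric,OLM,98.82
7,25,10,spectrophotometric,HCT,101.81
5,15,13.75,spectrophotometric,HCT,103.8
6,15,10,spectrophotometric,HCT,103.54
7,15,11.25,spectrophotometric,HCT,103.03
7,17.5,12.5,spectrophotometric,HCT,100.89
5,17.5,10,spectrophotometric,HCT,102.22
6,17.5,15,spectrophotometric,HCT,103.73
5,20,12.5,spectrophotometric,HCT,102.06
6,20,13.75,spectrophotometric,HCT,101.34
7,25,10,ann,AML,101.62
5,15,13.75,ann,AML,101.05
6,15,10,ann,AML,100.07
7,15,11.25,ann,AML,102.44
7,17.5,12.5,ann,AML,99.55
5,17.5,10,ann,AML,100.75
6,17.5,15,ann,AML,101.93
5,20,12.5,ann,AML,101.34
6,20,13.75,ann,AML,101.22
7,25,10,ann,OLM,98.2
5,15,13.75,ann,OLM,100.01
6,15,10,ann,OLM,97.28
7,15,11.25,ann,OLM,101.84
7,17.5,12.5,ann,OLM,98.11
5,17.5,10,ann,OLM,100.35
6,17.5,15,ann,OLM,101.89
5,20,12.5,ann,OLM,100.99
6,20,13.75,ann,OLM,99.9
7,25,10,ann,HCT,102.56
5,15,13.75,ann,HCT,101.2
6,15,10,ann,HCT,100.01
7,15,11.25,ann,HCT,102.58
7,17.5,12.5,ann,HCT,100
5,17.5,10,ann,HCT,100.89
6,17.5,15,ann,HCT,100
5,20,12.5,ann,HCT,100.35
6,20,13.75,ann,HCT,100.47
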