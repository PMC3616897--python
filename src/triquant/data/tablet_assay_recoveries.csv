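method,analyte,replicate,recovery_pct
spectrophotometric,AML,1,98.5
spectrophotometric,AML,2,98.5
spectrophotometric,AML,3,98.49
spectrophotometric,AML,4,98.51
spectrophotometric,AML,5,98.5
spectrophotometric,AML,6,97.15
spectrophotometric,OLM,1,99.19
spectrophotometric,OLM,2,98.98
spectrophotometric,OLM,3,98.67
spectrophotometric,OLM,4,98.20
spectrophotometric,OLM,5,97.87
spectrophotometric,OLM,6,96.94
spectrophotometric,HCT,1,97.66
spectrophotometric,HCT,2,97.18
spectrophotometric,HCT,3,96.91
spectrophotometric,HCT,4,96.36
spectrophotometric,HCT,5,96.6
spectrophotometric,HCT,6,95.99
ann,AML,1,99.04
ann,AML,2,100.08
ann,AML,3,99.28
ann,AML,4,100.48
ann,AML,5,100.4
ann,AML,6,96.96
ann,OLM,1,98.6
ann,OLM,2,96.86
ann,OLM,3,97.47
ann,OLM,4,98.28
ann,OLM,5,95.64
ann,OLM,6,97.54
ann,HCT,1,99.33
ann,HCT,2,97
ann,HCT,3,96.88
ann,HCT,4,97.34
ann,HCT,5,98.08
ann,HCT,6,96.01
reference,AML,1,98.79
reference,AML,2,98.46
reference,AML,3,99.62
reference,AML,4,98.28
reference,AML,5,98.44
reference,AML,6,97.78
reference,OLM,1,98.33
reference,OLM,2,97.87
reference,OLM,3,97.79
reference,OLM,4,97.13
reference,OLM,5,97.17
reference,OLM,6,96.42
reference,HCT,1,98.42
reference,HCT,2,98.07
reference,HCT,3,97.69
reference,HCT,4,97.27
reference,HCT,5,97.24
reference,HCT,6,96.33
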