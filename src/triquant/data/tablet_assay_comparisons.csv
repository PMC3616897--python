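method,analyte,t_stat,t_critical,f_stat,f_critical,consistent,comment
spectrophotometric,AML,0.842,2.228,1.241,5.050,yes,
spectrophotometric,OLM,1.955,2.228,1.497,5.050,yes,
spectrophotometric,HCT,0.994,2.228,1.574,5.050,yes,
ann,AML,1.608,2.228,4.307,5.050,no,printed t/F do not follow from the printed per-method means and variances
ann,OLM,1.355,2.228,3.338,5.050,no,printed t/F do not follow from the printed per-method means and variances
ann,HCT,1.73,2.228,1.574,5.050,no,printed t/F do not follow from the printed per-method means and variances
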