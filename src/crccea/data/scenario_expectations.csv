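item,arm,base_case,rate_3pct,rate_5pct
provider_cost,iFOBT,372.83,361.65,354.19
ly_per_patient,iFOBT,5.21,5.05,4.95
qaly_per_patient,iFOBT,3.44,3.34,3.27
provider_cost,genetic_testing,976.26,946.97,927.44
ly_per_patient,genetic_testing,6.13,5.95,5.82
qaly_per_patient,genetic_testing,4.97,4.82,4.72
cost_difference,both,603.424,585.318,573.25
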