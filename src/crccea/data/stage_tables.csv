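arm,stage,survival_mean,n,utility_mean,treatment_cost
iFOBT,I,6.71,6,0.87,3290.34
iFOBT,II,6.51,17,0.74,4771.01
iFOBT,III,5.65,54,0.72,6031.88
iFOBT,IV,2.84,23,0.11,6612.80
genetic_testing,I,6.71,10,0.85,3290.34
genetic_testing,II,6.51,60,0.82,4771.01
genetic_testing,III,5.65,25,0.77,6031.88
genetic_testing,IV,2.84,5,0.75,6612.80
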