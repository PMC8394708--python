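group,mobility_pct,self_care_pct,usual_activities_pct,pain_discomfort_pct,anxiety_depression_pct,utility_mean,utility_sd,utility_median,vas_mean,vas_sd,vas_median
all,37.4,30.2,38.7,51.4,44.1,0.787,0.273,0.861,73.58,18.47,78.20
iFOBT,36.6,29.9,40.9,43.3,42.7,0.801,0.264,0.890,73.10,17.28,77.50
genetic_testing,39.7,31.0,32.8,74.1,48.3,0.744,0.296,0.834,74.93,21.59,80.00
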