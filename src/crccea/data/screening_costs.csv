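arm,screening_cost_per_cohort,cohort_size
iFOBT,37283.53,100
genetic_testing,97626.33,100
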