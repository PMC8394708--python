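name,mean,ci_low,ci_high
building,2.568,2.565,2.571
equipment,0.300,0.298,0.303
human_resource,13.789,13.771,13.808
administration,56.329,56.238,56.421
utilities,2.787,2.770,2.803
maintenance,0.183,0.180,0.185
medication,18.751,18.741,18.760
consumables,0.407,0.404,0.409
laboratory,557.940,557.931,557.949
total,603.424,603.422,603.425
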