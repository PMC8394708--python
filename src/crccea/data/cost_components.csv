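arm,name,category,method,amount,se,currency,year
iFOBT,building,capital,top_down,62.48,0.09,USD,2019
iFOBT,equipment,capital,top_down,8.58,0.01,USD,2019
iFOBT,human_resource,recurrent,activity_based,43.23,0.48,USD,2019
iFOBT,administration,recurrent,top_down,118.13,0.47,USD,2019
iFOBT,utilities,recurrent,top_down,69.59,0.98,USD,2019
iFOBT,maintenance,recurrent,top_down,4.33,0.06,USD,2019
iFOBT,medication,recurrent,activity_based,19.45,0.66,USD,2019
iFOBT,consumables,recurrent,activity_based,1.15,0.01,USD,2019
iFOBT,laboratory,recurrent,activity_based,45.89,0.05,USD,2019
genetic_testing,building,capital,top_down,59.93,0.03,USD,2019
genetic_testing,equipment,capital,top_down,8.29,0.05,USD,2019
genetic_testing,human_resource,recurrent,activity_based,56.96,0.02,USD,2019
genetic_testing,administration,recurrent,top_down,174.85,0.10,USD,2019
genetic_testing,utilities,recurrent,top_down,66.75,0.05,USD,2019
genetic_testing,maintenance,recurrent,top_down,4.15,0.03,USD,2019
genetic_testing,medication,recurrent,activity_based,0.74,0.12,USD,2019
genetic_testing,consumables,recurrent,activity_based,0.73,0.09,USD,2019
genetic_testing,laboratory,recurrent,activity_based,603.86,0.06,USD,2019
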