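{
  "sha256": {
    "cost_components.csv": "279f305da469317ae9338bcf0a579f6105a00c625f78fedd8319f48a8e3ff5c5",
    "outcome_summary.csv": "fa54c50a1c61dbdf04b5cb0db5fcd1816c405bbc6f4acd7dc126dd5456d0acba",
    "published_cost_differences.csv": "d43f7c36b59b87b5ba729b00b6e55fa108d751d23b0c668ab0579cdac8c89b96",
    "scenario_expectations.csv": "24b4f2d8ff1d50770a654fb746c28124cae28b30d4f144dffb296a14a6416605",
    "screening_costs.csv": "2f823629c0b3a81e84b84fe95722e7bf8b789eb14587cc969fd5c6decc7e1c96",
    "stage_tables.csv": "4792fc9dd2baf5f507ad0366f71e7cc174582d141d304d177cdb6c1cff9d7284"
  }
}
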