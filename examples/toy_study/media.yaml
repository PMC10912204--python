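media:
- carbon_exchange: EX_carbon1_e
  carbon_uptake_max: 10.0
  condition_id: carbon1
  free_exchanges:
  - EX_spent_e
  oxygen_exchange: EX_o2_e
  oxygen_uptake_max: 20.0
- carbon_exchange: EX_carbon2_e
  carbon_uptake_max: 10.0
  condition_id: carbon2
  free_exchanges:
  - EX_spent_e
  oxygen_exchange: EX_o2_e
  oxygen_uptake_max: 20.0
- carbon_exchange: EX_carbon3_e
  carbon_uptake_max: 10.0
  condition_id: carbon3
  free_exchanges:
  - EX_spent_e
  oxygen_exchange: EX_o2_e
  oxygen_uptake_max: 20.0
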