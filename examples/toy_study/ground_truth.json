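{
 "planted_essential_genes": [
  "gC1a",
  "gC1b",
  "gC2",
  "gC3",
  "gN1",
  "gN2",
  "gT1"
 ],
 "planted_beneficial_reactions": {
  "carbon1": [
   "CAT_C1",
   "CORE1",
   "CORE2",
   "CORE3",
   "NT1",
   "NT2"
  ],
  "carbon2": [
   "CAT_C2",
   "CORE1",
   "CORE2",
   "CORE3",
   "NT1",
   "NT2"
  ],
  "carbon3": [
   "CAT_C3",
   "CORE1",
   "CORE2",
   "CORE3",
   "NT1",
   "NT2"
  ]
 },
 "planted_detrimental_reactions": {
  "carbon1": [
   "DRAIN"
  ],
  "carbon2": [
   "DRAIN"
  ],
  "carbon3": [
   "DRAIN"
  ]
 },
 "wildtype_growth": {
  "carbon1": 4.45,
  "carbon2": 4.45,
  "carbon3": 4.45
 }
}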