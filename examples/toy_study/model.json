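{
 "model_id": "toy_synthetic_seed0",
 "metabolites": [
  {
   "met_id": "o2_e",
   "compartment": "e",
   "name": "oxygen (extracellular)"
  },
  {
   "met_id": "o2_c",
   "compartment": "c",
   "name": "oxygen"
  },
  {
   "met_id": "spent_c",
   "compartment": "c",
   "name": "spent carbon/energy"
  },
  {
   "met_id": "spent_e",
   "compartment": "e",
   "name": "spent (extracellular)"
  },
  {
   "met_id": "prec1",
   "compartment": "c",
   "name": "shared catabolic precursor"
  },
  {
   "met_id": "core1",
   "compartment": "c",
   "name": "core intermediate 1"
  },
  {
   "met_id": "core2",
   "compartment": "c",
   "name": "core intermediate 2"
  },
  {
   "met_id": "bb",
   "compartment": "c",
   "name": "biosynthetic building block"
  },
  {
   "met_id": "aa",
   "compartment": "c",
   "name": "amino-acid-like precursor"
  },
  {
   "met_id": "nt_int",
   "compartment": "c",
   "name": "nucleotide intermediate"
  },
  {
   "met_id": "nt",
   "compartment": "c",
   "name": "nucleotide-like precursor"
  },
  {
   "met_id": "energy",
   "compartment": "c",
   "name": "energy carrier"
  },
  {
   "met_id": "carbon1_e",
   "compartment": "e",
   "name": "carbon source 1 (extracellular)"
  },
  {
   "met_id": "carbon1_c",
   "compartment": "c",
   "name": "carbon source 1"
  },
  {
   "met_id": "carbon2_e",
   "compartment": "e",
   "name": "carbon source 2 (extracellular)"
  },
  {
   "met_id": "carbon2_c",
   "compartment": "c",
   "name": "carbon source 2"
  },
  {
   "met_id": "carbon3_e",
   "compartment": "e",
   "name": "carbon source 3 (extracellular)"
  },
  {
   "met_id": "carbon3_c",
   "compartment": "c",
   "name": "carbon source 3"
  }
 ],
 "reactions": [
  {
   "rxn_id": "EX_o2_e",
   "stoichiometry": {
    "o2_e": -1
   },
   "lower_bound": -20.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "exchange",
   "ko_category": null
  },
  {
   "rxn_id": "T_O2",
   "stoichiometry": {
    "o2_e": -1,
    "o2_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "transport",
   "ko_category": null
  },
  {
   "rxn_id": "EX_spent_e",
   "stoichiometry": {
    "spent_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "exchange",
   "ko_category": null
  },
  {
   "rxn_id": "T_SPENT",
   "stoichiometry": {
    "spent_c": -1,
    "spent_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "transport",
   "ko_category": null
  },
  {
   "rxn_id": "EX_carbon1_e",
   "stoichiometry": {
    "carbon1_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "exchange",
   "ko_category": null
  },
  {
   "rxn_id": "TPT_C1",
   "stoichiometry": {
    "carbon1_e": -1,
    "carbon1_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gT1",
   "subsystem": "transport",
   "ko_category": null
  },
  {
   "rxn_id": "CAT_C1",
   "stoichiometry": {
    "carbon1_c": -1,
    "prec1": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gM1",
   "subsystem": "catabolism_carbon1",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "CATB_C1",
   "stoichiometry": {
    "carbon1_c": -1,
    "prec1": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gB1",
   "subsystem": "catabolism_carbon1",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "EX_carbon2_e",
   "stoichiometry": {
    "carbon2_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "exchange",
   "ko_category": null
  },
  {
   "rxn_id": "TPT_C2",
   "stoichiometry": {
    "carbon2_e": -1,
    "carbon2_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gT2",
   "subsystem": "transport",
   "ko_category": null
  },
  {
   "rxn_id": "CAT_C2",
   "stoichiometry": {
    "carbon2_c": -1,
    "prec1": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gM2",
   "subsystem": "catabolism_carbon2",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "CATB_C2",
   "stoichiometry": {
    "carbon2_c": -1,
    "prec1": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gB2",
   "subsystem": "catabolism_carbon2",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "EX_carbon3_e",
   "stoichiometry": {
    "carbon3_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "exchange",
   "ko_category": null
  },
  {
   "rxn_id": "TPT_C3",
   "stoichiometry": {
    "carbon3_e": -1,
    "carbon3_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gT3",
   "subsystem": "transport",
   "ko_category": null
  },
  {
   "rxn_id": "CAT_C3",
   "stoichiometry": {
    "carbon3_c": -1,
    "prec1": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gM3",
   "subsystem": "catabolism_carbon3",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "CATB_C3",
   "stoichiometry": {
    "carbon3_c": -1,
    "prec1": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gB3",
   "subsystem": "catabolism_carbon3",
   "ko_category": "carbohydrate_metabolism"
  },
  {
   "rxn_id": "CORE1",
   "stoichiometry": {
    "prec1": -1,
    "core1": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gC1a and gC1b",
   "subsystem": "core_biosynthesis",
   "ko_category": "amino_acid_metabolism"
  },
  {
   "rxn_id": "CORE2",
   "stoichiometry": {
    "core1": -1,
    "core2": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gC2",
   "subsystem": "core_biosynthesis",
   "ko_category": "amino_acid_metabolism"
  },
  {
   "rxn_id": "CORE3",
   "stoichiometry": {
    "core2": -1,
    "bb": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gC3",
   "subsystem": "core_biosynthesis",
   "ko_category": "amino_acid_metabolism"
  },
  {
   "rxn_id": "AA",
   "stoichiometry": {
    "bb": -1,
    "aa": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gAa or gAb",
   "subsystem": "amino_acid_biosynthesis",
   "ko_category": "amino_acid_metabolism"
  },
  {
   "rxn_id": "NT1",
   "stoichiometry": {
    "bb": -1,
    "nt_int": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gN1",
   "subsystem": "nucleotide_biosynthesis",
   "ko_category": "nucleotide_metabolism"
  },
  {
   "rxn_id": "NT2",
   "stoichiometry": {
    "nt_int": -1,
    "nt": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gN2",
   "subsystem": "nucleotide_biosynthesis",
   "ko_category": "nucleotide_metabolism"
  },
  {
   "rxn_id": "ENER",
   "stoichiometry": {
    "prec1": -1,
    "o2_c": -1,
    "energy": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "gEa or gEb",
   "subsystem": "energy_metabolism",
   "ko_category": "energy_metabolism"
  },
  {
   "rxn_id": "DRAIN",
   "stoichiometry": {
    "aa": -1,
    "energy": -1,
    "spent_c": 2
   },
   "lower_bound": 1.0,
   "upper_bound": 1000.0,
   "gpr": "gD",
   "subsystem": "overflow_metabolism",
   "ko_category": "energy_metabolism"
  },
  {
   "rxn_id": "MAINT",
   "stoichiometry": {
    "energy": -1,
    "spent_c": 1
   },
   "lower_bound": 0.2,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "maintenance",
   "ko_category": "energy_metabolism"
  },
  {
   "rxn_id": "BIOMASS",
   "stoichiometry": {
    "aa": -1,
    "nt": -1,
    "energy": -2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "",
   "subsystem": "biomass",
   "ko_category": null
  }
 ],
 "genes": [
  "gT1",
  "gM1",
  "gB1",
  "gT2",
  "gM2",
  "gB2",
  "gT3",
  "gM3",
  "gB3",
  "gC1a",
  "gC1b",
  "gC2",
  "gC3",
  "gAa",
  "gAb",
  "gN1",
  "gN2",
  "gEa",
  "gEb",
  "gD"
 ],
 "objective_reaction": "BIOMASS"
}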