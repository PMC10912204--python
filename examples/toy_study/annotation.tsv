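reaction_id	category_id	category_name
CAT_C1	carbohydrate_metabolism	carbohydrate_metabolism
CATB_C1	carbohydrate_metabolism	carbohydrate_metabolism
CAT_C2	carbohydrate_metabolism	carbohydrate_metabolism
CATB_C2	carbohydrate_metabolism	carbohydrate_metabolism
CAT_C3	carbohydrate_metabolism	carbohydrate_metabolism
CATB_C3	carbohydrate_metabolism	carbohydrate_metabolism
CORE1	amino_acid_metabolism	amino_acid_metabolism
CORE2	amino_acid_metabolism	amino_acid_metabolism
CORE3	amino_acid_metabolism	amino_acid_metabolism
AA	amino_acid_metabolism	amino_acid_metabolism
NT1	nucleotide_metabolism	nucleotide_metabolism
NT2	nucleotide_metabolism	nucleotide_metabolism
ENER	energy_metabolism	energy_metabolism
DRAIN	energy_metabolism	energy_metabolism
MAINT	energy_metabolism	energy_metabolism
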