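gene_id	source_label
gC1a	planted_essential
gC1b	planted_essential
gC2	planted_essential
gC3	planted_essential
gN1	planted_essential
gN2	planted_essential
gT1	planted_essential
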