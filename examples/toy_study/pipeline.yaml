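annotation_path: annotation.tsv
critical_genes_path: critical_genes.tsv
essential_genes:
- gC1a
- gC1b
- gC2
- gC3
- gN1
- gN2
- gT1
growth_path: growth.tsv
media_path: media.yaml
model_path: model.json
out_dir: run
seed: 0
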