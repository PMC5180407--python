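# Default knowledge-base configuration (small bundled catalogs for testing
# and worked examples; production use points these at curated files).
reference_range_genes: reference_range_genes.txt
acmg_genes: acmg_genes.txt
cosmic_ids: cosmic_ids.txt
cancer_genes: cancer_genes.txt
hotspots: hotspots.tsv
known_fusions: known_fusions.tsv
drug_targets: drug_targets.tsv
housekeeping_genes: housekeeping_genes.txt
patient_care_variants: patient_care_variants.tsv
af_threshold: 0.01
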