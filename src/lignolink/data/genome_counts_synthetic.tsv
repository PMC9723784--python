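# SYNTHETIC illustrative per-genome gene counts for the three consortium
# members (MAG1 Pseudomonas protegens, MAG4 Ochrobactrum gambitense,
# MAG5 Pristimantibacillus lignocellulolyticus).  These numbers are a
# constructed stand-in consistent with the reported genomic capabilities
# of these organisms (MAG1
# carries the catechol/benzoate/vanillate branches; MAG4 the
# 4-hydroxybenzoate and salicylate monooxygenases); they are not measured
# annotation counts.
genome_id	enzyme_id	gene_count
MAG1	catechol_12_dioxygenase	1
MAG1	muconate_cycloisomerase	2
MAG1	benzoate_12_dioxygenase	1
MAG1	vanillate_monooxygenase	2
MAG1	protocatechuate_34_dioxygenase	1
MAG4	hydroxybenzoate_3_monooxygenase	1
MAG4	salicylate_1_hydroxylase	1
MAG5	catechol_12_dioxygenase	1
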