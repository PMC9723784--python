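# Lignin-catabolizing enzymes and their LDCC substrates (beta-ketoadipate
# pathway and peripheral aromatic funnels).
id	name	ec	ko	substrates
muconate_cycloisomerase	muconate cycloisomerase	5.5.1.1	K01856	muconate
benzoate_12_dioxygenase	benzoate 1,2-dioxygenase	1.14.12.10	K05549,K05550	benzoate
vanillate_monooxygenase	vanillate monooxygenase	1.14.13.82	K03862	vanillate
hydroxybenzoate_3_monooxygenase	4-hydroxybenzoate 3-monooxygenase	1.14.13.2	K00481	hydroxybenzoate4
salicylate_1_hydroxylase	salicylate 1-hydroxylase	1.14.13.1	K00480	salicylate
catechol_12_dioxygenase	catechol 1,2-dioxygenase	1.13.11.1	K03381	catechol
protocatechuate_34_dioxygenase	protocatechuate 3,4-dioxygenase	1.13.11.3	K00448,K00449	protocatechuate
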