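# Built-in compound catalog: lignin-derived (LDCC) and plastic-derived (PDCC)
# chemical compounds central to aromatic-funnel plastic catabolism.  SMILES
# transcribed from each compound's standard structure and cross-checked by
# name against PubChem before release.
id	name	smiles	partition	xref
monomethyl_phthalate	monomethyl phthalate	COC(=O)c1ccccc1C(=O)O	PDCC
dihydroxyphthalate	3,4-dihydroxyphthalate	OC(=O)c1ccc(O)c(O)c1C(=O)O	PDCC
terephthalic_acid	terephthalic acid	OC(=O)c1ccc(cc1)C(=O)O	PDCC
hydroxybutyrate	3-hydroxybutyric acid	CC(O)CC(=O)O	PDCC
hydroxyvalerate	3-hydroxyvalerate	CCC(O)CC(=O)O	PDCC
vanillate	vanillate	COc1cc(ccc1O)C(=O)O	LDCC
muconate	cis,cis-muconic acid	OC(=O)C=CC=CC(=O)O	LDCC
benzoate	benzoic acid	OC(=O)c1ccccc1	LDCC
catechol	catechol	Oc1ccccc1O	LDCC
protocatechuate	protocatechuate	Oc1ccc(C(=O)O)cc1O	LDCC
hydroxybenzoate4	4-hydroxybenzoate	Oc1ccc(cc1)C(=O)O	LDCC
salicylate	salicylate	Oc1ccccc1C(=O)O	LDCC
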