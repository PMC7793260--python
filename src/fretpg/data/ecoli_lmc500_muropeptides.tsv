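# Muropeptide percent-peak-area table (HPLC, cellosyl digest) of E. coli LMC500
# strains carrying no plasmid or the indicated mKO expression plasmids.
# Values are the means of two biological replicates. Species names follow the
# Glauner nomenclature; dimer/trimer totals are explicit "total" rows because
# the printed species rows do not cover every minor peak of those classes.
species	oligomer_class	row_type	peptide_length	modification	LMC500	mKO	mKO_PBP2WT	mKO_PBP2L61R	mKO_GlpT
Di	monomer	species	2	none	1.4	1.6	1.3	1.2	1.4
Tri	monomer	species	3	none	5.0	5.0	5.0	4.0	4.7
Tetra	monomer	species	4	none	41.6	41.0	41.3	43.3	41.8
TetraAnh	monomer	species	4	anhydro	0.9	1.0	1.0	0.7	1.0
TetraLysArg	monomer	species	4	lys_arg	3.7	3.4	3.5	3.0	3.4
Dimers_total	dimer	total		none	40.5	40.8	40.2	41.7	40.7
TetraTri	dimer	species	3	none	3.1	3.0	3.0	2.2	2.9
TetraTetra	dimer	species	4	none	36.0	36.3	35.0	37.1	36.0
TetraTetraAnh	dimer	species	4	anhydro	2.0	2.1	2.2	1.7	2.0
TetraTetraLysArg	dimer	species	4	lys_arg	1.6	1.7	1.5	1.2	1.6
Trimers_total	trimer	total		none	4.4	4.6	4.8	3.8	4.5
ChainEndsAnh	chain_ends	chain_ends		anhydro	2.3	2.4	2.5	1.9	2.3
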