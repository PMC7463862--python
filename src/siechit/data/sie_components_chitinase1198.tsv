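# Published per-snapshot-averaged SIE term components (kcal/mol) for the
# three chitinase 1198 / chitin-oligomer complexes, used as worked-example
# input for components-only scoring. Columns name the oligomer length and
# which GlcNAc unit (from the nonreducing end) carries the Asp440 contact.
term	glcnac12_unit2	glcnac12_unit3	glcnac3_unit2
inter_vdw	-92.36	-90.26	-66.44
inter_coulomb	-23.33	-36.72	-23.91
reaction_field	39.14	58.26	33.64
cavity	-14.81	-15.98	-11.09
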