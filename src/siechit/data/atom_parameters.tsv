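# Minimal self-consistent per-atom parameter set for the toy pocket /
# pseudo-GlcNAc systems generated by siechit.synthetic.
# Charges are united-atom style (implicit hydrogens folded into the heavy
# atom) so each pseudo-sugar unit is net neutral and the ASP carboxylate
# carries -1 e. LJ well depths / Rmin-half follow common all-atom
# force-field magnitudes; boundary_radius is a vdW-like dielectric radius
# (scaled globally by rho at solve time).
# Rows with residue '*' and atom '*' are element fallbacks.
residue	atom	element	charge	lj_epsilon	lj_rmin_half	boundary_radius
ASP	CG	C	0.62	0.0860	1.9080	1.70
ASP	OD1	O	-0.81	0.2100	1.6612	1.52
ASP	OD2	O	-0.81	0.2100	1.6612	1.52
POC	CP	C	0.00	0.1094	1.9080	1.70
POC	CQ	C	0.25	0.1094	1.9080	1.70
NAG	C1	C	0.95	0.1094	1.9080	1.70
NAG	N2	N	-0.15	0.1700	1.8240	1.55
NAG	O7	O	-0.57	0.2100	1.6612	1.52
NAG	O3	O	-0.23	0.2104	1.7210	1.52
HOH	O	O	-0.834	0.1520	1.7683	1.52
HOH	H	H	0.417	0.0157	0.3000	1.20
*	*	C	0.00	0.0860	1.9080	1.70
*	*	N	0.00	0.1700	1.8240	1.55
*	*	O	0.00	0.2100	1.6612	1.52
*	*	H	0.00	0.0157	0.6000	1.20
*	*	S	0.00	0.2500	2.0000	1.80
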