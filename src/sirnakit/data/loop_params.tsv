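# Coarse loop penalties (kcal/mol) for the simplified secondary-structure
# energy model: destabilizing free energies of hairpin, bulge and internal
# loops by number of unpaired bases, plus multiloop affine terms.  Sizes
# beyond the largest tabulated value are extrapolated with the
# Jacobson-Stockmayer term 1.75 * RT * ln(n / n_max), RT = 0.616 kcal/mol.
# schema: kind	size	penalty_kcal_mol
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
internal	2	1.5
internal	3	1.6
internal	4	1.7
internal	5	2.0
internal	6	2.0
internal	7	2.2
internal	8	2.3
multiloop	closing	3.4
multiloop	branch	0.4
multiloop	unpaired	0.0
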