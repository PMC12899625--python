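# Watson-Crick RNA/RNA nearest-neighbor free energies, dG37 in kcal/mol
# (Xia et al. 1998 unified parameters). Key = 5'->3' dinucleotide on the
# reference strand, paired to its perfect complement; symmetry-equivalent
# stacks carry identical values. Special rows: init = duplex initiation,
# terminal_au = per-terminal A-U pair penalty.
# schema: key	dg37_kcal_mol
AA	-0.93
UU	-0.93
AU	-1.10
UA	-1.33
CU	-2.08
AG	-2.08
CA	-2.11
UG	-2.11
GU	-2.24
AC	-2.24
GA	-2.35
UC	-2.35
CG	-2.36
GG	-3.26
CC	-3.26
GC	-3.42
init	4.09
terminal_au	0.45
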