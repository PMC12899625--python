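# Energy-class modification pattern table.
#
# Nucleotides are classed by pairing energy: X = low-energy (A/U),
# Y = high-energy (G/C).  Each case row maps a segment class-string to a
# per-position sugar assignment (m = 2'-O-methyl, f = 2'-fluoro) for each
# of the three design columns: two antisense variants (set1_even,
# set2_odd) and the sense column.  Terminal dinucleotide cases carry a
# 5'/3' prefix.  Cells are reproduced verbatim from the published pattern
# table, including the sense-column 5'XY cell "5'fXfX", whose class
# letters disagree with its case label (applied positionwise by sugar
# letter, classes taken from the actual strand), and the absence of a
# 5'YY row.
version: 1
columns: [set1_even, set2_odd, sense]
cases:
  XXX:    {set1_even: mXmXfX,   set2_odd: mXfXmX,   sense: fXmXmX}
  YYY:    {set1_even: mYmYfY,   set2_odd: mYfYmY,   sense: fYmYmY}
  XYX:    {set1_even: mXfYmX,   set2_odd: fXmYfX,   sense: fXfYmX}
  YXY:    {set1_even: fYmXfY,   set2_odd: mYfXmY,   sense: mYmXfY}
  "5'XY": {set1_even: "5'mXfY", set2_odd: "5'fXmY", sense: "5'fXfX"}
  "5'YX": {set1_even: "5'mYfX", set2_odd: "5'fYmX", sense: "5'fYfX"}
  "5'XX": {set1_even: "5'mXmX", set2_odd: "5'fXfX", sense: "5'mXfX"}
  "3'XY": {set1_even: "3'mXfY", set2_odd: "3'fXmY", sense: "3'mXfX"}
  "3'YX": {set1_even: "3'fYmX", set2_odd: "3'mYfX", sense: "3'mYmX"}
  "3'XX": {set1_even: "3'fXfX", set2_odd: "3'mXmX", sense: "3'fXmX"}
  "3'YY": {set1_even: "3'mYmY", set2_odd: "3'fYfY", sense: "3'fYmY"}
# Split forms for homogeneous runs longer than 4, applied to 4-mer
# segments in every column (derived rows, not part of the printed table):
derived_cases:
  XXXX: {set1_even: mXfXfXmX, set2_odd: mXfXfXmX, sense: mXfXfXmX}
  YYYY: {set1_even: fYmYmYfY, set2_odd: fYmYmYfY, sense: fYmYmYfY}
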