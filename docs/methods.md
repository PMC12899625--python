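# Methods

This note records the models behind each module, the parameters that
matter, and the design choices made where the published heuristics leave
the details open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Duplex geometry and coordinates

A candidate duplex is a 21/21-mer pair: the sense (passenger) strand is the
transcript window itself, the antisense (guide) strand its reverse
complement. The duplex core is sense positions 1–19 paired with antisense
positions 3–21; the last two nucleotides of each strand are unpaired 3′
overhangs. All positions are 1-based, counted 5′→3′ on the named strand —
"antisense position 6" means the sixth base from the guide's 5′ end.
Strand length is configurable between 19 and 23; every default matches the
canonical 21-mer geometry with 2-nt overhangs.

## First-pass rules

The three classical selection rule sets are re-implemented from their
original publications, since design servers only name them:

* **Ui-Tei (class Ia)**: A/U at the guide 5′ terminus; G/C at the passenger
  5′ terminus; ≥ 4 A/U among guide positions 1–7; no G/C stretch of ≥ 10 nt.
* **Reynolds (8 criteria, pass ≥ 6 points)**: on the 19-nt sense core —
  GC 30–52 % (+1); +1 per A/U at positions 15–19; no strong internal
  inverted repeat (+1); A19 (+1); A3 (+1); U10 (+1); G/C19 (−1); G13 (−1).
  The original internal-repeat criterion is a hairpin-melting cutoff; here
  it is rendered as the absence of a self-complementary inverted repeat
  with stem ≥ 5 nt and loop ≥ 3 nt, which is deterministic and
  parameter-free.
* **Amarzguioui**: GC 31.6–57.9 % on the sense core plus at least 3 of 4
  positional features (G/C at sense 1; A at sense 6; A/U at sense 19;
  neither U1 nor G19).

Rules combine by union (default) or intersection; the flags for all three
are always reported per candidate, so the choice can be revisited after the
fact.

## Scoring engine

Fourteen criteria (see `sirnakit.scoring` for the table). Choices that the
scheme's prose leaves open:

* **"GC repeats fewer than 3 times and AT repeats fewer than 4 times"**
  (c4) is read as *tandem dinucleotide* repeats — `(GC)₃`/`(CG)₃` and
  `(AU)₄`/`(UA)₄` anywhere in the sense strand fail the criterion. The
  alternative run-length reading (≥ 3 consecutive G/C) would fail known
  active sequences ending in `GGG`, so it was rejected.
* **TT overhang** (c5) accepts `TT` or `UU` at the sense 3′ end
  (configurable); unmodified candidate strands frequently carry
  sequence-derived overhangs and then simply score 0 here.
* **Criterion weights** enumerate to 16 (twelve 1-point sequence criteria,
  the 2-point energy valley, the 1-point accessibility criterion and the
  2-point off-target criterion) although the scheme is conventionally
  described as a 15-point score. Which criterion the original tally
  down-weights is not documented, so both constants
  (`WEIGHT_SUM = 16`, `NOMINAL_MAX_POINTS = 15`) are exported, attached to
  every ScoreCard's metadata and printed in the report header, rather than
  silently reconciled.
* **Selection** uses strict inequality: total > 10.
* Criteria whose context inputs are missing (no transcript for
  accessibility, no background for off-targets) award 0 and are marked
  *not evaluated* — scoring a bare duplex is always possible.
* Ranking is total-descending with deterministic tie-breaks: valley passed,
  then off-target clearance passed, then lower target position.

The auxiliary composition checks (A/U:G/C balance ≈ 50 % with a ±10
percentage-point tolerance, islet-size distribution, 4–6-mer homo-energy
runs, terminal-dinucleotide rules) are reported as named booleans and never
enter the point total.

## Thermodynamics

Per-step duplex free energies use the Watson–Crick RNA/RNA
nearest-neighbor ΔG°37 parameters of Xia et al. (1998), shipped as a TSV
fixture (`data/nn_rna_wc_dg37.tsv`: 16 dinucleotide stacks, +4.09 kcal/mol
initiation, +0.45 kcal/mol per terminal A-U pair) and swappable via
`NNParamSet.from_tsv`. Profiles cover the 19-nt duplex core only; overhangs
are single-stranded and carry no stacking term.

The **energy valley** statistic: a positional window a..b maps to
dinucleotide steps a..b−1 (the steps with both bases inside the window);
the criterion is true when the mean step ΔG inside the window exceeds (is
less negative than) the mean over all remaining steps by a margin, default
0.5 kcal/mol. A mean-vs-rest statistic was chosen over a minimum-window
statistic because "valley" is otherwise undefined; both are implemented
(`statistic="mean_vs_rest" | "min_window"`) and the detector is provably
monotone in the margin. The **end differential** (mean of the first k
steps minus mean of the last k, default k = 4, computed on the guide
strand) and the **step 10–11 differential** quantify the 5′/3′ asymmetry
that favors guide-strand loading.

## Secondary structure / accessibility

The folder is a simplified Zuker-style dynamic program over nested
Watson–Crick structures: stacking energies from the same nearest-neighbor
table; hairpin, bulge and internal loops carry coarse size-dependent
penalties (`data/loop_params.tsv`) with Jacobson–Stockmayer extrapolation
(1.75·RT·ln(n/n_max), RT = 0.616 kcal/mol) beyond the tabulated sizes;
multiloops cost an affine 3.4 + 0.4/branch kcal/mol. G-U wobbles,
dangling ends, coaxial stacking and pseudoknots are not modeled — the
folder exists to estimate *site accessibility*, not to compete with a full
Turner-2004 implementation, and an adapter hook (`fold_window(engine=...)`)
delegates to an external folding program when one is wanted. Interior
loops are capped at 30 unpaired bases; windows are capped at 200 nt
(default 80). Minimum hairpin loop is 3 nt. The traceback examines
decompositions in a fixed order, so identical input yields an identical
dot-bracket.

The accessibility criterion folds the 80-nt window centered on the target
site (clamped at transcript ends) and passes when ≤ 50 % of site bases are
paired in the MFE structure. Window size and threshold are configuration,
not constants — neither is prescribed by the scheme this implements. An
alternative reading (fold the siRNA strand itself rather than the mRNA
window) exists; target-site accessibility was chosen because that is what
the criterion's stated purpose — detecting stable structure in the mRNA
target region — measures.

The DP is verified against an independent exhaustive enumeration of all
nested structures for sequences ≤ 14 nt (200 random cases in the test
suite); the enumerator evaluates each structure by direct loop
decomposition and never calls the DP.

## Off-target screening

"Percent homology" is plain ungapped identity with the query length (21)
as denominator; gaps would count as mismatches, which makes an ungapped
sliding-window scan exact — hence no gapped aligner is needed. Both
strands are screened against both orientations of every background record;
hits above the threshold (default 85 %) are reported sorted by identity
then subject id, independent of record order. The seeded scan anchors on
exact k-mers with k derived from the threshold by pigeonhole (identity
> 85 % on a 21-mer allows ≤ 3 mismatches, so k = ⌊21/4⌋ = 5 can never miss
a hit); small subjects (< 2 kb) are scanned exhaustively. Clearance
excludes the intended target by record id, not by sequence, so paralog
hits are never masked. Whether published "% homology" figures derive from
identity alone or coverage×identity is not stated anywhere authoritative;
plain identity is implemented and labeled as such.

## Modification patterns

Nucleotides are classed by pairing energy — X = A/U (two hydrogen bonds),
Y = G/C (three). The strand is partitioned into the 5′ terminal
dinucleotide, internal 3/4-mer chunks, and the 3′ terminal dinucleotide;
each chunk's class string is looked up in the pattern table
(`data/modification_patterns.yaml`), which maps it to per-position m/f
sugar assignments in three columns (two antisense variant families and a
sense column). The table is shipped verbatim from its printed source,
including two quirks that are reproduced rather than repaired: there is no
5′YY row, and the sense-column 5′XY cell reads `5'fXfX` (class letters
disagreeing with the case label — cells are applied positionwise by sugar
letter, classes always taken from the actual strand). Homogeneous runs
longer than 4 split into 4-mers with the `mXfXfXmX` / `fYmYmYfY` forms,
shipped as derived rows.

Internal chunking is a deterministic dynamic program that minimizes the
number of chunks whose label is missing from the table — this is what
merges single-base islands into `XYX`/`YXY` junction cases — with ties
preferring a homogeneous 4-chunk, then a 3-chunk, then any 4-chunk,
scanning 5′→3′. For lengths where both terminals plus a 3/4-partition are
arithmetically impossible (5, 6 and 9 nt), the 3′ terminal yields to a
final internal chunk so the partition stays exact. Segments whose label
has no row raise an error naming the case by default; `on_missing="2ome"`
falls back to all-2′-O-methyl for that segment (the fully 2′-OMe
substituted control chemistry), which is what the pipeline-facing code
uses. Mapping from published variant *numbers* to specific
table columns is not reconstructible from the main description, so the
engine is table+column driven rather than recipe driven.

The junction report (`junction_pattern_check`) flags, without scoring, the
motifs shared by the most active designs: `mYfYmXfX` high→low-energy
bridges, mixed energy classes at positions 10–11, a `5'mXfX` start and
`3'mXmX` / `3'fYmY` ends.

## Mass, yield and expression calculators

Oligo masses are accumulated as whole-molecule **elemental formulas**
(nucleoside formulas; +CH₂ for 2′-OMe; −OH+F for 2′-F; −O for 2′-deoxy;
+HPO₃−H₂O per internucleotide bridge; −O+S per phosphorothioate) and
evaluated with IUPAC average atomic weights, rather than summing
pre-rounded per-residue constants — rounding therefore never compounds
across a 21-mer. Convention: free-acid (H⁺) form, 5′-OH and 3′-OH termini;
monoisotopic mode available but off by default; a conjugated ligand (e.g.
a triantennary GalNAc plus linker) enters as one configurable adduct mass,
with no structural model. Reported to 2 decimals. An independent oracle in
the tests recomputes an all-ribo 21-mer from nucleoside-5′-monophosphate
formulas (agreement required within 0.05 g/mol).

Yield planning is the product of per-stage efficiencies, each in (0, 1];
percent rendering rounds half-up to an integer. ΔΔCq follows the standard
definitions: ΔCt = Ct(target) − Ct(housekeeping) per replicate, ΔΔCt =
group-mean difference (experimental − control), fold change = 2^(−ΔΔCt).
Published fold-change values from expression experiments cannot be
re-derived without the control group's raw ΔCt values, so only the formula
layer is validated, on closed-form cases.

## Synthetic fixtures — what they do and do not show

The generator draws A/U-biased flanks (70 % A/U, UTR-like) around planted
features: an engineered 21-mer
(`GCAGCGCGAUUAACUUAUAUU`) constructed to satisfy every sequence criterion,
all three first-pass rule sets, and — via adenosine-rich flanking (25 nt
per side, on by default) — the accessibility criterion; and background
records carrying copies of the site with a chosen number of substitutions
(m ≤ 3 lies above the 85 % identity bar, m ≥ 4 below). All randomness
flows from one integer seed; the manifest records ground truth.

Passing tests on these fixtures demonstrate that the machinery recovers
planted signal exactly and deterministically. They do not demonstrate
biological efficacy: real transcripts have correlated composition,
structure the simplified folder underestimates, and off-target landscapes
vastly larger than a three-record background. Problem sizes in the test
suite (transcripts of 120–200 nt, backgrounds of 3–4 × 150–400 nt, fold
windows of 80 nt) were chosen as the smallest sizes at which every planted
feature is non-trivially embedded in random context.

## Known limitations

* The folder's coarse loop model and WC-only pairing make its MFE values
  model-specific; only site accessibility (paired fraction), not the MFE
  itself, feeds the score.
* Off-target identity ignores expression levels and seed-region weighting;
  a 2-point clearance criterion is a blunt instrument by design.
* Modified-sugar thermodynamic increments are not modeled; energy profiles
  describe the unmodified duplex.
* Melting temperatures, salt corrections and isotope envelopes are out of
  scope.
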