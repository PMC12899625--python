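# sirnakit

A toolkit for the rational design of small interfering RNAs (siRNAs) and
their chemically modified, conjugate-ready derivatives. It covers the full
in-silico side of an siRNA discovery campaign against a target mRNA:

1. **Candidate enumeration** — every 21-nt window of the transcript becomes
   a sense/antisense duplex (2-nt 3′ overhangs, 19-bp core), optionally
   pre-filtered by the three classical published rule sets (Ui-Tei,
   Reynolds, Amarzguioui).
2. **Multi-criterion scoring** — each duplex is scored against fourteen
   criteria: global and region-wise GC content, a nearest-neighbor
   "energy valley" in sense positions 9–14 (ΔG of the central steps less
   negative than the rest, favoring RISC-mediated cleavage), tandem-repeat
   and positional nucleotide rules, target-site accessibility in the
   minimum-free-energy fold of the local mRNA window, and off-target
   clearance at ≤ 85 % homology against a background transcriptome.
   Candidates scoring > 10 points are flagged selectable.
3. **Chemical modification** — an energy-class pattern engine: nucleotides
   are classed X (A/U, low pairing energy) or Y (G/C, high), the strand is
   segmented into terminal dinucleotides and internal 3/4-mers, and each
   segment receives 2′-O-methyl (m) / 2′-fluoro (f) sugars from a pattern
   table; designs are emitted in `mN`/`fN`/`rN`/`dN` notation with optional
   `s` phosphorothioate markers.
4. **Lab support** — average molecular weight of modified oligos (free-acid
   H⁺ form, from elemental composition), multi-stage synthesis yield
   planning, and ΔΔCq relative-expression analysis
   (fold change = 2^(−ΔΔCt)).

A synthetic fixture generator plants engineered target sites and
off-targets with known ground truth, so the whole pipeline runs and is
tested fully offline.

## Worked example

Generate a synthetic transcript with one planted high-quality site, run the
full design pipeline, and inspect the top of the ranked report:

```sh
sirnakit fixtures --outdir fx --seed 17 --transcript-len 150 --site-positions 60
sirnakit design --transcript fx/transcript.fasta --background fx/background.fasta --out report.tsv
head -5 report.tsv
```

```
# sirnakit design report; config sha256:a53b14f23511
# criterion weights sum to 16; nominal maximum 15 points
name	target_start	sense	antisense	c1	c2	c3	c4	c5	c6	c7	c8	c9	c10	c11	c12	c13	c14	total	selectable
synthetic_transcript_60	60	GCAGCGCGAUUAACUUAUAUU	AAUAUAAGUUAAUCGCGCUGC	1	1	2	1	1	1	1	1	1	1	1	1	1	2	16	True
synthetic_transcript_10	10	CUAGAUUCUAUUAUGUAGUGA	UCACUACAUAAUAGAAUCUAG	0	0	2	1	0	1	1	1	0	1	1	0	1	2	11	True
```

The planted site at position 60 passes every criterion — one point each for
the twelve sequence rules except the energy valley (c3) and off-target
clearance (c14), which carry two — for the maximum 16 points, and ranks
first. (The criterion weights enumerate to 16 although the scheme is
conventionally quoted as a 15-point score; the report header records both.)

The lab calculators work directly from notation strings and stage lists:

```sh
$ sirnakit mass --notation "mAfUmAfAmAfUmGmUmCmUmGfCmUfUmGfCmUfUmGfGmG"
6889.28
$ sirnakit yield --stages 0.49,0.55,0.95
total: 0.2560 (26%)
$ sirnakit modify AUAUA --column set2_odd
fAfUmAfUmA
```

The first command is the average molecular weight (g/mol, free-acid H⁺
form) of a 21-mer 2′-OMe/2′-F antisense strand; the second chains three
stage efficiencies (49 %, 55 %, 95 %) into a 26 % total synthesis yield;
the third applies the odd-variant modification pattern column to a toy
5-mer.

Every subcommand (`enumerate`, `score`, `design`, `offtarget`, `fold`,
`modify`, `mass`, `yield`, `ddcq`, `fixtures`) is a thin wrapper over the
library API — see `docs/methods.md` for the models and parameter choices.

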