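"""Energy-class chemical-modification engine.

Classifies each nucleotide by pairing energy (A/U -> X "low-energy",
G/C -> Y "high-energy"), partitions the strand into terminal dinucleotides
and internal 3-/4-mer segments, and assigns 2'-O-methyl (m) / 2'-fluoro (f)
sugars per segment from a pattern table, emitting designs in mN/fN
notation.  Also reports the junction/terminal motifs (mYfYmXfX patterns,
5'mXfX, 3'mXmX / 3'fYmY, the position 10-11 class pair) shared by the most
active designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .core import ModifiedOligo, Residue, RnaStrand

_DEFAULT_TABLE: Optional["PatternTable"] = None


def classify_energy(strand: Union[RnaStrand, str]) -> str:
    """Positionwise energy-class string: A/U -> X, G/C -> Y (T as U)."""
    seq = strand.seq if isinstance(strand, RnaStrand) else strand.upper()
    if not seq:
        raise ValueError("empty strand")
    out = []
    for b in seq:
        if b in "AUT":
            out.append("X")
        elif b in "GC":
            out.append("Y")
        else:
            raise ValueError(f"unknown base {b!r}")
    return "".join(out)


@dataclass(frozen=True)
class Segment:
    start: int   # 1-based position of first residue
    classes: str
    terminal: str = ""  # "", "5'", "3'"

    @property
    def label(self) -> str:
        return self.terminal + self.classes

    @property
    def length(self) -> int:
        return len(self.classes)


class PatternTable:
    """Case-label -> per-column sugar assignments (m/f strings)."""

    COLUMNS = ("set1_even", "set2_odd", "sense")

    def __init__(self, cases: Dict[str, Dict[str, str]], version: int = 1):
        self.cases = cases
        self.version = version
        for label, row in cases.items():
            body = label[2:] if label[:2] in ("5'", "3'") else label
            for col, cell in row.items():
                if col not in self.COLUMNS:
                    raise ValueError(f"unknown column {col!r} in case {label!r}")
                sugars = cell_sugars(cell)
                if len(sugars) != len(body):
                    raise ValueError(
                        f"case {label!r}, column {col!r}: cell {cell!r} length "
                        f"mismatch with case"
                    )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PatternTable":
        raw = yaml.safe_load(Path(path).read_text())
        cases = dict(raw["cases"])
        cases.update(raw.get("derived_cases", {}))
        return cls(cases, version=raw.get("version", 1))

    def sugars_for(self, label: str, column: str) -> str:
        if column not in self.COLUMNS:
            raise ValueError(f"unknown column {column!r}; expected one of {self.COLUMNS}")
        if label not in self.cases:
            raise KeyError(f"no pattern row for case {label!r}")
        return "".join(cell_sugars(self.cases[label][column]))


def cell_sugars(cell: str) -> List[str]:
    """Sugar letters of a table cell, e.g. "5'mXfY" -> ['m', 'f']."""
    body = cell[2:] if cell[:2] in ("5'", "3'") else cell
    if len(body) % 2:
        raise ValueError(f"malformed cell {cell!r}")
    sugars = []
    for i in range(0, len(body), 2):
        s, c = body[i], body[i + 1]
        if s not in "mf" or c not in "XY":
            raise ValueError(f"malformed cell {cell!r} at token {body[i:i+2]!r}")
        sugars.append(s)
    return sugars


def default_table() -> PatternTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("sirnakit.data") / "modification_patterns.yaml"
        with resources.as_file(ref) as p:
            _DEFAULT_TABLE = PatternTable.from_yaml(p)
    return _DEFAULT_TABLE


def _partitionable(n: int) -> bool:
    return n == 0 or (n >= 3 and n != 5)


def segment(
    classes: str, max_island: int = 3, table: Optional[PatternTable] = None
) -> List[Segment]:
    """Partition a class string into 5' dinucleotide, internal 3/4-chunks,
    3' dinucleotide.

    The internal chunking is a deterministic dynamic program that minimizes
    the number of chunks whose label has no row in the pattern table (this
    is what merges short islands with their neighbors into XYX/YXY triplet
    cases at junctions, and splits homogeneous runs longer than 4 into the
    4-mer/triplet split forms).  Ties prefer, in order: a homogeneous
    4-chunk, a 3-chunk, any 4-chunk.  The result is always an exact
    partition of the strand.
    """
    table = table or default_table()
    L = len(classes)
    if L < 5:
        raise ValueError(f"strand of {L} nt too short to segment (need >= 5)")
    # Claim both terminal dinucleotides when the internal region is
    # 3/4-partitionable; otherwise (L = 5, 6, 9) the 3' terminal yields to a
    # final internal chunk so the partition stays exact.
    three_prime_terminal = _partitionable(L - 4)
    inner = classes[2 : L - 2] if three_prime_terminal else classes[2:]
    n = len(inner)
    if not _partitionable(n):
        raise ValueError(
            f"internal region of {n} nt cannot be partitioned into 3/4-mers"
        )

    known = set(table.cases)
    NONE = (float("inf"), ())

    # f[i]: (min missing-row count, chunk-length tuple) for inner[i:]
    f: List[Tuple[float, Tuple[int, ...]]] = [NONE] * (n + 1)
    f[n] = (0, ())
    for i in range(n - 1, -1, -1):
        options: List[int] = []
        if i + 4 <= n and len(set(inner[i : i + 4])) == 1:
            options.append(4)
        if i + 3 <= n:
            options.append(3)
        if i + 4 <= n and 4 not in options:
            options.append(4)
        best = NONE
        for w in options:
            if not _partitionable(n - i - w):
                continue
            cost = 0 if inner[i : i + w] in known else 1
            sub_cost, sub_lens = f[i + w]
            cand = (cost + sub_cost, (w,) + sub_lens)
            if cand[0] < best[0]:
                best = cand
        f[i] = best
    assert f[0][0] != float("inf")

    segments = [Segment(start=1, classes=classes[:2], terminal="5'")]
    pos = 2  # 0-based offset into full string
    for w in f[0][1]:
        segments.append(Segment(start=pos + 1, classes=classes[pos : pos + w]))
        pos += w
    if three_prime_terminal:
        segments.append(Segment(start=L - 1, classes=classes[L - 2 :], terminal="3'"))
    return segments


def apply_patterns(
    strand: Union[RnaStrand, str],
    table: Optional[PatternTable] = None,
    column: str = "set2_odd",
    on_missing: str = "error",
    name: str = "",
) -> ModifiedOligo:
    """Assign m/f sugars per segment from the pattern table.

    Bases are never changed; the output serializes to mN/fN notation.
    ``on_missing`` controls segments whose case label has no table row:
    ``error`` (default) raises naming the case; ``2ome`` falls back to
    all-2'-O-methyl for that segment (the full-2'-OMe control chemistry).
    """
    table = table or default_table()
    seq = strand.seq if isinstance(strand, RnaStrand) else strand.upper()
    classes = classify_energy(seq)
    sugars = [""] * len(seq)
    for seg in segment(classes, table=table):
        try:
            seg_sugars = table.sugars_for(seg.label, column)
        except KeyError:
            if on_missing == "2ome":
                seg_sugars = "m" * seg.length
            else:
                raise KeyError(
                    f"no pattern row for case {seg.label!r} "
                    f"(positions {seg.start}..{seg.start + seg.length - 1})"
                ) from None
        for offset, s in enumerate(seg_sugars):
            sugars[seg.start - 1 + offset] = s
    assert all(sugars)
    residues = tuple(Residue(base=b, sugar=s) for b, s in zip(seq, sugars))
    return ModifiedOligo(residues, name=name or getattr(strand, "name", ""))


def apply_full_2ome(strand: Union[RnaStrand, str], name: str = "") -> ModifiedOligo:
    """Uniform 2'-O-methyl design (the fully substituted control duplex)."""
    seq = strand.seq if isinstance(strand, RnaStrand) else strand.upper()
    residues = tuple(Residue(base=b, sugar="m") for b in seq)
    return ModifiedOligo(residues, name=name or getattr(strand, "name", ""))


def junction_pattern_check(oligo: ModifiedOligo) -> Dict[str, object]:
    """Report the sugar/class motifs shared by the most active designs.

    Returned fields (booleans and 1-based positions only, no scoring):

    * ``myfymxfx_positions``: start positions of mYfYmXfX junctions
      (sugars m,f,m,f over classes Y,Y,X,X) -- the most effective
      high-to-low-energy island bridge pattern;
    * ``classes_10_11`` and ``mixed_energy_10_11``: the class pair at
      positions 10-11 and whether both energy classes are present there;
    * ``five_prime_mxfx``: 5' terminus is mX fX;
    * ``three_prime_mxmx`` / ``three_prime_fymy``: 3' terminus motifs.
    """
    classes = classify_energy(oligo.bases)
    sugars = oligo.sugars
    n = len(oligo)

    positions = []
    for i in range(n - 3):
        if sugars[i : i + 4] == "mfmf" and classes[i : i + 4] == "YYXX":
            positions.append(i + 1)

    report: Dict[str, object] = {
        "myfymxfx_positions": positions,
        "five_prime_mxfx": (
            n >= 2 and sugars[:2] == "mf" and classes[:2] == "XX"
        ),
        "three_prime_mxmx": (
            n >= 2 and sugars[-2:] == "mm" and classes[-2:] == "XX"
        ),
        "three_prime_fymy": (
            n >= 2 and sugars[-2:] == "fm" and classes[-2:] == "YY"
        ),
    }
    if n >= 11:
        report["classes_10_11"] = classes[9:11]
        report["mixed_energy_10_11"] = len(set(classes[9:11])) == 2
    else:
        report["classes_10_11"] = None
        report["mixed_energy_10_11"] = None
    return report
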