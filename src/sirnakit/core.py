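"""Core sequence types, the modified-oligo notation grammar, and FASTA I/O.

The notation for chemically modified oligonucleotides is a concatenation of
two-character tokens ``<sugar><base>`` read 5'->3':

* ``rN`` -- unmodified ribonucleoside
* ``mN`` -- 2'-O-methyl ribonucleoside
* ``fN`` -- 2'-fluoro ribonucleoside
* ``dN`` -- 2'-deoxyribonucleoside

An ``s`` immediately following a token marks a phosphorothioate (PS)
internucleotide linkage on the 3' side of that residue; the default linkage
is phosphodiester (PO).  Parsing is case-insensitive; serialization is
canonical uppercase-base / lowercase-sugar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
EXTENDED_ALPHABET = frozenset("ACGUT")  # T allowed for DNA overhangs

_COMPLEMENT = {"A": "U", "U": "A", "T": "A", "G": "C", "C": "G"}

SUGARS = ("r", "m", "f", "d")
LINKAGES = ("po", "ps")


class SequenceError(ValueError):
    """Invalid sequence content or geometry."""


class NotationError(ValueError):
    """Malformed modified-oligo notation string."""


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class RnaStrand:
    """An unmodified 5'->3' strand over {A,C,G,U} (T tolerated for overhangs)."""

    seq: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"strand {self.name!r}: empty sequence")
        bad = set(self.seq) - EXTENDED_ALPHABET
        if bad:
            raise SequenceError(
                f"strand {self.name!r}: characters {sorted(bad)} outside alphabet ACGUT"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, i) -> str:
        return self.seq[i]

    def base_at(self, pos: int) -> str:
        """1-based positional access, counted 5'->3'."""
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"position {pos} outside 1..{len(self.seq)}")
        return self.seq[pos - 1]


def reverse_complement(strand: Union[RnaStrand, str]) -> Union[RnaStrand, str]:
    """Watson-Crick reverse complement (RNA convention: A<->U, G<->C, T->A).

    An involution on pure-RNA sequences; applying it twice returns the input.
    """
    if isinstance(strand, RnaStrand):
        rc = "".join(_COMPLEMENT[b] for b in reversed(strand.seq))
        suffix = "_rc"
        name = strand.name[:-3] if strand.name.endswith(suffix) else strand.name + suffix
        return RnaStrand(rc, name=name)
    return "".join(_COMPLEMENT[b] for b in reversed(strand.upper()))


def _core_equal(a: str, b: str) -> bool:
    """Compare sequences treating T as U (pairing equivalence)."""
    return a.replace("T", "U") == b.replace("T", "U")


@dataclass(frozen=True)
class SirnaDuplex:
    """A sense/antisense siRNA pair with 3' overhangs and target coordinates.

    Geometry (default 21/21 with 2-nt overhangs): the duplex core is sense
    positions 1..L-overhang paired with antisense positions overhang+1..L;
    the last ``overhang_len`` nt of each strand are unpaired 3' extensions.
    ``target_start`` is the 1-based position of the sense window on the
    transcript.
    """

    sense: RnaStrand
    antisense: RnaStrand
    target_start: int = 1
    overhang_len: int = 2
    name: str = ""

    MIN_LEN = 19
    MAX_LEN = 23

    def __post_init__(self) -> None:
        ls, la = len(self.sense), len(self.antisense)
        if ls != la:
            raise SequenceError(f"duplex {self.name!r}: strand lengths differ ({ls} vs {la})")
        if not self.MIN_LEN <= ls <= self.MAX_LEN:
            raise SequenceError(
                f"duplex {self.name!r}: strand length {ls} outside {self.MIN_LEN}..{self.MAX_LEN}"
            )
        core = ls - self.overhang_len
        sense_core = self.sense.seq[:core]
        anti_core = self.antisense.seq[self.overhang_len:]
        if not _core_equal(reverse_complement(sense_core), anti_core):
            raise SequenceError(
                f"duplex {self.name!r}: antisense core is not the reverse "
                f"complement of the sense core"
            )
        if self.target_start < 1:
            raise SequenceError(f"duplex {self.name!r}: target_start must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sense)

    @property
    def core_len(self) -> int:
        return self.length - self.overhang_len

    @property
    def sense_core(self) -> str:
        return self.sense.seq[: self.core_len]

    @property
    def antisense_core(self) -> str:
        return self.antisense.seq[self.overhang_len :]


@dataclass(frozen=True)
class Residue:
    base: str
    sugar: str  # r / m / f / d
    linkage3: str = "po"

    def __post_init__(self) -> None:
        if self.base not in EXTENDED_ALPHABET:
            raise NotationError(f"unknown base {self.base!r}")
        if self.sugar not in SUGARS:
            raise NotationError(f"unknown sugar code {self.sugar!r}")
        if self.linkage3 not in LINKAGES:
            raise NotationError(f"unknown linkage {self.linkage3!r}")


@dataclass(frozen=True)
class ModifiedOligo:
    """An ordered list of residues carrying base, sugar chemistry and 3' linkage."""

    residues: Tuple[Residue, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if not self.residues:
            raise NotationError(f"oligo {self.name!r}: empty residue list")
        if self.residues[-1].linkage3 != "po":
            raise NotationError(
                f"oligo {self.name!r}: last residue carries a dangling 3' linkage"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bases(self) -> str:
        return "".join(r.base for r in self.residues)

    @property
    def sugars(self) -> str:
        return "".join(r.sugar for r in self.residues)

    def to_strand(self, name: str = "") -> RnaStrand:
        """Underlying base sequence (T preserved) as a plain strand."""
        return RnaStrand(self.bases, name=name or self.name)


_TOKEN_RE = re.compile(r"([rmfd])([acgut])|(s)", re.IGNORECASE)


def parse_modified(notation: str, name: str = "") -> ModifiedOligo:
    """Parse mN/fN/rN/dN notation (with optional ``s`` PS infix) into residues.

    Raises :class:`NotationError` naming the byte offset of the first
    offending character; a trailing ``s`` (PS linkage with no following
    residue) and an empty string are rejected.
    """
    if not notation:
        raise NotationError("empty notation string")
    residues: List[List] = []  # [base, sugar, linkage3]
    pos = 0
    n = len(notation)
    while pos < n:
        m = _TOKEN_RE.match(notation, pos)
        if m is None:
            raise NotationError(
                f"unknown token at offset {pos}: {notation[pos:pos + 2]!r}"
            )
        if m.group(3):  # PS marker
            if not residues:
                raise NotationError(f"'s' linkage marker at offset {pos} precedes any residue")
            if residues[-1][2] == "ps":
                raise NotationError(f"duplicate 's' marker at offset {pos}")
            residues[-1][2] = "ps"
        else:
            residues.append([m.group(2).upper(), m.group(1).lower(), "po"])
        pos = m.end()
    if not residues:
        raise NotationError("notation contains no residues")
    if residues[-1][2] == "ps":
        raise NotationError("trailing 's': dangling 3' phosphorothioate linkage")
    return ModifiedOligo(
        tuple(Residue(b, s, l) for b, s, l in residues), name=name
    )


def serialize_modified(oligo: ModifiedOligo) -> str:
    """Canonical notation string; inverse of :func:`parse_modified`."""
    out = []
    for r in oligo.residues:
        out.append(r.sugar + r.base)
        if r.linkage3 == "ps":
            out.append("s")
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA I/O (multi-record, wrap 60)
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path], rna: bool = True) -> List[RnaStrand]:
    """Read a FASTA file into strands, converting T->U when ``rna`` is set.

    An empty file yields an empty list; a record with an empty sequence is a
    format error (reported with its record index).
    """
    path = Path(path)
    strands: List[RnaStrand] = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        if first != ">":
            raise FastaFormatError(f"{path}: line 1: expected '>' header, got {first!r}")
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {i} ({rec.id!r}): empty sequence")
        if rna:
            seq = seq.replace("T", "U")
        try:
            strands.append(RnaStrand(seq, name=rec.id))
        except SequenceError as e:
            raise FastaFormatError(f"{path}: record {i}: {e}") from e
    return strands


def write_fasta(records: Iterable[RnaStrand], path: Union[str, Path], wrap: int = 60) -> None:
    """Write strands as multi-record FASTA at a fixed wrap width (default 60)."""
    seqrecs = [
        SeqRecord(Seq(s.seq), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(records, start=1)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecs)


def duplexes_to_tsv(duplexes: Sequence[SirnaDuplex], path: Union[str, Path]) -> None:
    """TSV export of duplex tables (name, sense, antisense, target_start)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "name": [d.name for d in duplexes],
            "sense": [d.sense.seq for d in duplexes],
            "antisense": [d.antisense.seq for d in duplexes],
            "target_start": [d.target_start for d in duplexes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
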