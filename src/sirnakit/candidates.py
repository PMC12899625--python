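"""Candidate duplex enumeration and first-pass published-rule filters.

Enumeration slides a window (default 21 nt) along the transcript; the sense
strand is the window itself, the antisense (guide) strand its reverse
complement, giving the standard 21/21 geometry with 2-nt 3' overhangs
(duplex core = sense 1-19 paired with antisense 3-21).

The first-pass filters are re-implementations of the three published siRNA
selection rule sets offered by siDirect-style design servers:

* **Ui-Tei** (Ui-Tei et al. 2004, class Ia): A/U at the guide 5' terminus;
  G/C at the passenger 5' terminus; at least 4 A/U in the guide 5' terminal
  7 bases; no G/C stretch of 10 or more bases.
* **Reynolds** (Reynolds et al. 2004, 8-criterion score, pass at >= 6):
  computed on the 19-nt sense core -- GC 30-52% (+1); one point per A/U at
  positions 15-19 (up to +5); no strong internal inverted repeat (+1);
  A at 19 (+1); A at 3 (+1); U at 10 (+1); G/C at 19 (-1); G at 13 (-1).
  The internal-repeat criterion (originally a hairpin-Tm cutoff) is
  rendered as the absence of a self-complementary inverted repeat with a
  stem of 5 or more bases.
* **Amarzguioui** (Amarzguioui & Prydz 2004): GC content 31.6-57.9% on the
  sense core, plus at least 3 of 4 positional features -- G/C at sense
  position 1; A at sense position 6; A/U at sense position 19; and neither
  U at position 1 nor G at position 19.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

from .core import RnaStrand, SirnaDuplex, reverse_complement

KNOWN_RULES = frozenset({"uitei", "reynolds", "amarzguioui"})


@dataclass
class CandidateSet:
    """Enumerated duplexes plus per-duplex published-rule flags."""

    transcript_id: str
    duplexes: List[SirnaDuplex] = field(default_factory=list)
    rule_flags: Dict[int, Dict[str, bool]] = field(default_factory=dict)
    # rule_flags keyed by target_start

    def __len__(self) -> int:
        return len(self.duplexes)


def enumerate_candidates(
    transcript: RnaStrand, length: int = 21, overhang: int = 2
) -> CandidateSet:
    """One duplex per window position: L - length + 1 candidates.

    A transcript shorter than the window yields an empty set with a warning.
    """
    cands = CandidateSet(transcript_id=transcript.name)
    L = len(transcript)
    if L < length:
        warnings.warn(
            f"transcript {transcript.name!r} ({L} nt) shorter than window ({length} nt); "
            "no candidates",
            stacklevel=2,
        )
        return cands
    seq = transcript.seq
    for start in range(L - length + 1):
        window = seq[start : start + length]
        sense = RnaStrand(window, name=f"{transcript.name}_{start + 1}_S")
        antisense = RnaStrand(
            reverse_complement(window), name=f"{transcript.name}_{start + 1}_aS"
        )
        cands.duplexes.append(
            SirnaDuplex(
                sense=sense,
                antisense=antisense,
                target_start=start + 1,
                overhang_len=overhang,
                name=f"{transcript.name}_{start + 1}",
            )
        )
    return cands


# ---------------------------------------------------------------------------
# Published rule predicates (evaluated on the 19-nt duplex core)
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


def uitei_rule(duplex: SirnaDuplex) -> bool:
    guide = duplex.antisense.seq
    sense_core = duplex.sense_core
    cond1 = guide[0] in "AU"
    cond2 = sense_core[0] in "GC"
    cond3 = sum(b in "AU" for b in guide[:7]) >= 4
    cond4 = re.search(r"[GC]{10,}", duplex.sense.seq) is None
    return cond1 and cond2 and cond3 and cond4


def _has_inverted_repeat(seq: str, min_stem: int = 5, min_loop: int = 3) -> bool:
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - 2 * min_stem - min_loop + 1):
        stem = seq[i : i + min_stem]
        # a downstream occurrence of the stem's reverse complement closes a hairpin
        tail = seq[i + min_stem + min_loop :]
        if reverse_complement(stem) in tail:
            return True
    return False


def reynolds_score(duplex: SirnaDuplex) -> int:
    s = duplex.sense_core  # 19-mer, 1-based positions below
    score = 0
    if 0.30 <= _gc_fraction(s) <= 0.52:
        score += 1
    score += sum(b in "AU" for b in s[14:19])  # positions 15-19, +1 each
    if not _has_inverted_repeat(s):
        score += 1
    if s[18] == "A":
        score += 1
    if s[2] == "A":
        score += 1
    if s[9] == "U":
        score += 1
    if s[18] in "GC":
        score -= 1
    if s[12] == "G":
        score -= 1
    return score


def reynolds_rule(duplex: SirnaDuplex, threshold: int = 6) -> bool:
    return reynolds_score(duplex) >= threshold


def amarzguioui_rule(duplex: SirnaDuplex) -> bool:
    s = duplex.sense_core
    if not 0.316 <= _gc_fraction(s) <= 0.579:
        return False
    features = [
        s[0] in "GC",
        s[5] == "A",
        s[18] in "AU",
        s[0] != "U" and s[18] != "G",
    ]
    return sum(features) >= 3


_RULE_FUNCS = {
    "uitei": uitei_rule,
    "reynolds": reynolds_rule,
    "amarzguioui": amarzguioui_rule,
}


def first_pass_filter(
    cands: CandidateSet, rules: Set[str], mode: str = "union"
) -> CandidateSet:
    """Retain duplexes passing the union (default) or intersection of rules.

    ``rule_flags`` is populated for *all* input duplexes regardless of
    retention.  The empty rule set is a no-op filter.  Filtering is
    idempotent and monotone (output duplexes are a subset of the input).
    """
    unknown = set(rules) - KNOWN_RULES
    if unknown:
        raise ValueError(f"unknown rule name(s): {sorted(unknown)}")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")

    out = CandidateSet(transcript_id=cands.transcript_id)
    for d in cands.duplexes:
        flags = {name: _RULE_FUNCS[name](d) for name in sorted(KNOWN_RULES)}
        out.rule_flags[d.target_start] = flags
        if not rules:
            keep = True
        elif mode == "union":
            keep = any(flags[r] for r in rules)
        else:
            keep = all(flags[r] for r in rules)
        if keep:
            out.duplexes.append(d)
    return out
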