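"""Multi-criterion efficacy/specificity scoring of siRNA duplexes.

Each duplex is evaluated against fourteen criteria; points are awarded per
criterion met and summed into a total.  Twelve are sequence criteria
(positions are 1-based from the 5' end of the named 21-mer strand), one is
the target-site accessibility (secondary-structure) criterion, and one the
off-target clearance criterion:

==== ===================================================================== ======
id    criterion                                                            points
==== ===================================================================== ======
c1    global GC content 36-52%                                              1
c2    antisense GC: positions 2-7 <= 19% AND positions 8-18 >= 52%          1
c3    energy valley in sense positions 9-14 (nearest-neighbor profile)      2
c4    tandem (GC) repeats < 3 and (AU) repeats < 4                          1
c5    TT (or UU) 3' overhang on the sense strand                            1
c6    A/U at the antisense 5' end                                           1
c7    G/C at the sense 5' end                                               1
c8    A at antisense position 6                                             1
c9    A at sense positions 3 and 19                                         1
c10   no G/C at sense position 19                                           1
c11   no G at sense position 13                                             1
c12   U at sense position 10                                                1
c13   target-site accessibility in the MFE fold of the local mRNA window    1
c14   off-target clearance at <= 85% homology against the background        2
==== ===================================================================== ======

The enumerated weights sum to 16 (``WEIGHT_SUM``) while the scheme is
conventionally quoted as a 15-point score (``NOMINAL_MAX_POINTS``); which
criterion the original tally down-weights is not documented, so both
constants are surfaced in ScoreCard metadata and in TSV exports instead of
silently reconciling them.  Duplexes scoring strictly more than the
selection threshold (default 10) are flagged selectable.

Criteria whose context inputs are absent (no transcript for c13, no
background for c14) award 0 points and are marked "not evaluated" rather
than erroring, so partial contexts degrade gracefully.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import RnaStrand, SirnaDuplex
from . import fold as fold_mod
from . import offtarget as ot_mod
from .thermo import NNParamSet, energy_valley, nn_profile

#: per-criterion weights as enumerated above
CRITERION_WEIGHTS: Dict[str, int] = {
    "c1": 1, "c2": 1, "c3": 2, "c4": 1, "c5": 1, "c6": 1, "c7": 1,
    "c8": 1, "c9": 1, "c10": 1, "c11": 1, "c12": 1, "c13": 1, "c14": 2,
}

#: sum of the enumerated weights
WEIGHT_SUM: int = sum(CRITERION_WEIGHTS.values())  # == 16

#: the conventional stated maximum of this scoring scheme (see module docs)
NOMINAL_MAX_POINTS: int = 15

#: "more than N points" selection rule -- strict inequality
DEFAULT_SELECTION_THRESHOLD: int = 10


@dataclass(frozen=True)
class CriterionResult:
    id: str
    passed: bool
    points_awarded: int
    detail: str = ""
    evaluated: bool = True


@dataclass
class ScoreCard:
    """Per-criterion breakdown plus total for one duplex."""

    duplex: SirnaDuplex
    criteria: List[CriterionResult] = field(default_factory=list)
    threshold: int = DEFAULT_SELECTION_THRESHOLD
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(c.points_awarded for c in self.criteria)

    @property
    def selectable(self) -> bool:
        return self.total > self.threshold

    def result(self, cid: str) -> CriterionResult:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def passed(self, cid: str) -> bool:
        return self.result(cid).passed


@dataclass
class ScoringContext:
    """Shared inputs for criteria that look beyond the duplex itself.

    ``transcript`` enables the accessibility criterion (c13);
    ``background`` the off-target criterion (c14).  Thermodynamic and
    folding parameters default to the bundled tables.
    """

    transcript: Optional[RnaStrand] = None
    background: Optional[Sequence[RnaStrand]] = None
    target_id: Optional[str] = None
    nn_params: Optional[NNParamSet] = None
    valley_window: Tuple[int, int] = (9, 14)
    valley_margin: float = 0.5
    fold_window: int = 80
    accessibility_threshold: float = 0.5
    offtarget_threshold_pct: float = 85.0
    overhang_accept: Tuple[str, ...] = ("TT", "UU")
    selection_threshold: int = DEFAULT_SELECTION_THRESHOLD


def _gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


def _crit(cid: str, passed: bool, detail: str = "", evaluated: bool = True) -> CriterionResult:
    points = CRITERION_WEIGHTS[cid] if (passed and evaluated) else 0
    return CriterionResult(cid, passed and evaluated, points, detail, evaluated)


def score_duplex(duplex: SirnaDuplex, ctx: Optional[ScoringContext] = None) -> ScoreCard:
    """Evaluate all criteria; a pure function of (duplex, context).

    Strands must be long enough for the positional criteria (>= 19 nt,
    enforced by the duplex type itself).
    """
    ctx = ctx or ScoringContext()
    s = duplex.sense.seq
    a = duplex.antisense.seq
    if len(s) < 19:
        raise ValueError("strands too short for positional criteria")
    crits: List[CriterionResult] = []

    # c1: global GC content of the duplex (sense 21-mer)
    gc = _gc_fraction(s)
    crits.append(_crit("c1", 0.36 <= gc <= 0.52, f"GC {gc:.1%}"))

    # c2: antisense GC content, positions 2-7 and 8-18
    gc_seed = _gc_fraction(a[1:7])
    gc_central = _gc_fraction(a[7:18])
    crits.append(
        _crit(
            "c2",
            gc_seed <= 0.19 and gc_central >= 0.52,
            f"aS GC 2-7 {gc_seed:.1%}, 8-18 {gc_central:.1%}",
        )
    )

    # c3: energy valley in sense positions 9-14 (2 points)
    profile = nn_profile(duplex, params=ctx.nn_params, strand="sense")
    valley = energy_valley(profile, window=ctx.valley_window, margin=ctx.valley_margin)
    crits.append(_crit("c3", valley, f"window {ctx.valley_window}, margin {ctx.valley_margin}"))

    # c4: tandem dinucleotide repeats (GC)n < 3 and (AU)n < 4 in the sense strand
    su = s.replace("T", "U")
    gc_rep = re.search(r"(GC){3,}|(CG){3,}", su) is not None
    au_rep = re.search(r"(AU){4,}|(UA){4,}", su) is not None
    crits.append(_crit("c4", not gc_rep and not au_rep))

    # c5: TT (or UU) 3' overhang on the sense strand
    ov = s[-duplex.overhang_len:] if duplex.overhang_len else ""
    crits.append(_crit("c5", ov in ctx.overhang_accept, f"overhang {ov!r}"))

    # c6: A/U at the antisense 5' end
    crits.append(_crit("c6", a[0] in "AU", f"aS pos 1 = {a[0]}"))

    # c7: G/C at the sense 5' end
    crits.append(_crit("c7", s[0] in "GC", f"S pos 1 = {s[0]}"))

    # c8: A at antisense position 6
    crits.append(_crit("c8", a[5] == "A", f"aS pos 6 = {a[5]}"))

    # c9: A at sense positions 3 and 19
    crits.append(_crit("c9", s[2] == "A" and s[18] == "A", f"S pos 3/19 = {s[2]}/{s[18]}"))

    # c10: no G/C at sense position 19
    crits.append(_crit("c10", s[18] not in "GC", f"S pos 19 = {s[18]}"))

    # c11: no G at sense position 13
    crits.append(_crit("c11", s[12] != "G", f"S pos 13 = {s[12]}"))

    # c12: U at sense position 10
    crits.append(_crit("c12", s[9] in "UT", f"S pos 10 = {s[9]}"))

    # c13: target-site accessibility (1 point); needs the transcript
    if ctx.transcript is not None:
        accessible = fold_mod.accessibility_criterion(
            ctx.transcript,
            duplex.target_start,
            site_len=len(s),
            window=ctx.fold_window,
            threshold=ctx.accessibility_threshold,
        )
        crits.append(_crit("c13", accessible))
    else:
        crits.append(_crit("c13", False, "not evaluated: no transcript", evaluated=False))

    # c14: off-target clearance at <= 85% homology (2 points); needs background
    if ctx.background:
        hits = ot_mod.scan(duplex, ctx.background, threshold_pct=ctx.offtarget_threshold_pct)
        clear = ot_mod.clearance(hits, target_id=ctx.target_id)
        n_foreign = sum(h.subject_id != ctx.target_id for h in hits)
        crits.append(_crit("c14", clear, f"{n_foreign} off-target hit(s)"))
    else:
        crits.append(_crit("c14", False, "not evaluated: no background", evaluated=False))

    card = ScoreCard(
        duplex=duplex,
        criteria=crits,
        threshold=ctx.selection_threshold,
        metadata={
            "weight_sum": WEIGHT_SUM,
            "nominal_max_points": NOMINAL_MAX_POINTS,
            "weight_note": (
                "enumerated criterion weights sum to 16; the scheme is "
                "conventionally quoted as 15 points"
            ),
        },
    )
    assert card.total <= WEIGHT_SUM
    return card


def rank_candidates(cards: Sequence[ScoreCard]) -> List[ScoreCard]:
    """Descending by total; ties broken by valley passed, then off-target
    clearance passed, then lower target_start.  Deterministic."""
    return sorted(
        cards,
        key=lambda c: (
            -c.total,
            not c.passed("c3"),
            not c.passed("c14"),
            c.duplex.target_start,
        ),
    )


def cards_to_frame(cards: Sequence[ScoreCard]):
    """One row per duplex, one column per criterion, plus totals."""
    import pandas as pd

    rows = []
    for card in cards:
        row: Dict[str, object] = {
            "name": card.duplex.name,
            "target_start": card.duplex.target_start,
            "sense": card.duplex.sense.seq,
            "antisense": card.duplex.antisense.seq,
        }
        for c in card.criteria:
            row[c.id] = c.points_awarded
            if not c.evaluated:
                row[c.id] = pd.NA
        row["total"] = card.total
        row["selectable"] = card.selectable
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["weight_sum"] = WEIGHT_SUM
    df.attrs["nominal_max_points"] = NOMINAL_MAX_POINTS
    return df


# ---------------------------------------------------------------------------
# Auxiliary sequence-composition checks
# ---------------------------------------------------------------------------

def table5_checks(
    duplex: SirnaDuplex, balance_tol: float = 0.10
) -> Dict[str, bool]:
    """Named auxiliary composition checks on the sense strand.

    * ``au_gc_balance``: A/U vs G/C content within ``balance_tol`` of 50:50;
    * ``islands_2_3``: same-class runs (islets) no longer than 3 nt;
    * ``homo_run_4_6``: at least one 4-6 nt run of a single energy class;
    * ``terminal_rule``: first two bases one energy class, last two the
      other;
    * ``conditional_34_rule``: if positions 1-2 are A/U then 3-4 are G/C,
      and if 1-2 are G/C then 3-4 are A/U (vacuously true when positions
      1-2 are mixed).
    """
    s = duplex.sense.seq.replace("T", "U")
    classes = "".join("X" if b in "AU" else "Y" for b in s)

    gc = _gc_fraction(s)
    balance = abs(gc - 0.5) <= balance_tol

    runs = [len(m.group(0)) for m in re.finditer(r"X+|Y+", classes)]
    islands_2_3 = max(runs) <= 3
    homo_run_4_6 = any(4 <= r <= 6 for r in runs)

    first2, last2 = classes[:2], classes[-2:]
    terminal_rule = (
        len(set(first2)) == 1 and len(set(last2)) == 1 and first2[0] != last2[0]
    )

    pos34 = classes[2:4]
    if first2 == "XX":
        conditional = pos34 == "YY"
    elif first2 == "YY":
        conditional = pos34 == "XX"
    else:
        conditional = True

    return {
        "au_gc_balance": balance,
        "islands_2_3": islands_2_3,
        "homo_run_4_6": homo_run_4_6,
        "terminal_rule": terminal_rule,
        "conditional_34_rule": conditional,
    }
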