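"""Off-target homology screening against a background transcript set.

Both siRNA strands are screened against every background record in both
orientations.  "Percent homology" is plain ungapped identity with the query
length (21) as denominator, evaluated over every length-L subject window;
a hit is any window whose identity exceeds the clearance threshold
(default 85%).  The scan is seed-anchored: an exact k-mer match is required
to trigger window evaluation, with k chosen from the threshold by the
pigeonhole principle (identity > 85% on a 21-mer allows at most 3
mismatches, so k = floor(21 / 4) = 5 can never miss a hit).  Small
subjects are scanned exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import RnaStrand, SirnaDuplex, reverse_complement


@dataclass(frozen=True)
class OfftargetHit:
    query_strand: str            # "antisense" | "sense"
    subject_id: str
    subject_span: Tuple[int, int]  # 1-based inclusive, forward-strand coords
    identity_pct: float
    alignment: Tuple[str, str]   # (query, matched subject window)
    subject_orientation: str = "+"


def max_mismatches(query_len: int, threshold_pct: float) -> int:
    """Largest mismatch count m with identity (L-m)/L still > threshold."""
    m = 0
    while (query_len - (m + 1)) / query_len * 100.0 > threshold_pct:
        m += 1
    return m


def pigeonhole_k(query_len: int, threshold_pct: float) -> int:
    """Seed length guaranteeing no missed hit above the threshold."""
    return max(1, query_len // (max_mismatches(query_len, threshold_pct) + 1))


def _window_identity(query: str, window: str) -> float:
    matches = sum(a == b for a, b in zip(query, window))
    return 100.0 * matches / len(query)


def _scan_subject_exhaustive(
    query: str, subject: str, threshold_pct: float
) -> List[Tuple[int, float, str]]:
    """All (offset, identity, window) with identity > threshold."""
    L = len(query)
    out = []
    for off in range(len(subject) - L + 1):
        window = subject[off : off + L]
        ident = _window_identity(query, window)
        if ident > threshold_pct:
            out.append((off, ident, window))
    return out


def _scan_subject_seeded(
    query: str, subject: str, threshold_pct: float, k: int
) -> List[Tuple[int, float, str]]:
    L = len(query)
    if len(subject) < L:
        return []
    index: Dict[str, List[int]] = {}
    for off in range(len(subject) - k + 1):
        index.setdefault(subject[off : off + k], []).append(off)
    candidate_offsets = set()
    for qoff in range(L - k + 1):
        seed = query[qoff : qoff + k]
        for soff in index.get(seed, ()):
            w = soff - qoff
            if 0 <= w <= len(subject) - L:
                candidate_offsets.add(w)
    out = []
    for off in sorted(candidate_offsets):
        window = subject[off : off + L]
        ident = _window_identity(query, window)
        if ident > threshold_pct:
            out.append((off, ident, window))
    return out


def scan(
    duplex: SirnaDuplex,
    background: Sequence[RnaStrand],
    threshold_pct: float = 85.0,
    k: Optional[int] = None,
    exhaustive_below: int = 2000,
    method: str = "auto",
) -> List[OfftargetHit]:
    """Find all background windows above the homology threshold.

    Both duplex strands are queried against both orientations of every
    subject.  ``method`` is ``auto`` (exhaustive for subjects shorter than
    ``exhaustive_below``, seeded otherwise), ``seeded`` or ``exhaustive``.
    Hits are sorted by descending identity, then subject id, strand, span --
    independent of background record order.
    """
    if not background:
        raise ValueError("empty background: off-target criterion unevaluable")
    if not 0 < threshold_pct <= 100:
        raise ValueError(f"threshold {threshold_pct} outside (0, 100]")
    queries = {
        "antisense": duplex.antisense.seq.replace("T", "U"),
        "sense": duplex.sense.seq.replace("T", "U"),
    }
    hits: List[OfftargetHit] = []
    for rec in background:
        subj_fwd = rec.seq.replace("T", "U")
        n = len(subj_fwd)
        for orientation, subj in (("+", subj_fwd), ("-", reverse_complement(subj_fwd))):
            for strand_name, query in queries.items():
                use_k = k if k is not None else pigeonhole_k(len(query), threshold_pct)
                if method == "exhaustive" or (method == "auto" and n < exhaustive_below):
                    found = _scan_subject_exhaustive(query, subj, threshold_pct)
                elif method in ("seeded", "auto"):
                    found = _scan_subject_seeded(query, subj, threshold_pct, use_k)
                else:
                    raise ValueError(f"unknown scan method {method!r}")
                for off, ident, window in found:
                    if orientation == "+":
                        span = (off + 1, off + len(query))
                    else:
                        span = (n - (off + len(query)) + 1, n - off)
                    hits.append(
                        OfftargetHit(
                            query_strand=strand_name,
                            subject_id=rec.name,
                            subject_span=span,
                            identity_pct=round(ident, 2),
                            alignment=(query, window),
                            subject_orientation=orientation,
                        )
                    )
    hits.sort(
        key=lambda h: (
            -h.identity_pct,
            h.subject_id,
            h.query_strand,
            h.subject_span,
            h.subject_orientation,
        )
    )
    return hits


def clearance(hits: Sequence[OfftargetHit], target_id: Optional[str] = None) -> bool:
    """True iff no hit remains after excluding the intended target record.

    Exclusion is by record id (not sequence), so genuine paralog hits on
    other records are never masked.
    """
    return not any(h.subject_id != target_id for h in hits)


def hits_report(hits: Sequence[OfftargetHit]):
    """Tabular report (strand, subject, span, % homology) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "strand": [h.query_strand for h in hits],
            "subject": [h.subject_id for h in hits],
            "orientation": [h.subject_orientation for h in hits],
            "start": [h.subject_span[0] for h in hits],
            "end": [h.subject_span[1] for h in hits],
            "homology_pct": [h.identity_pct for h in hits],
        }
    )
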