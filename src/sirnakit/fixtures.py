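"""Synthetic fixture generation: transcripts with planted target sites and
backgrounds with planted off-targets.

The generator makes the whole design pipeline testable offline.  Flanking
sequence is drawn A/U-biased (70% A/U), mimicking UTR-like composition and
keeping accidental high-scoring windows and stable secondary structure
rare; planted features are exact, so ground truth in the manifest is
recoverable by construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .core import RnaStrand, write_fasta

#: A 21-mer engineered to satisfy every sequence criterion of the scoring
#: engine (GC 38%, seed/central antisense GC split, A/U-rich valley in sense
#: positions 9-14 flanked by G/C stacks, UU overhang, all positional rules)
#: as well as all three first-pass published rule sets.
ALL_CRITERIA_SITE = "GCAGCGCGAUUAACUUAUAUU"

_BASES = "ACGU"


@dataclass(frozen=True)
class PlantedOfftarget:
    """An off-target planted into a background record: the site's antisense
    target (i.e. the site itself) copied with ``mismatches`` substitutions."""

    record: int          # background record index (0-based)
    mismatches: int
    position: int = -1   # 1-based plant position; -1 = centered


@dataclass
class FixtureSpec:
    transcript_len: int = 300
    site_positions: Tuple[int, ...] = ()      # 1-based starts of planted sites
    site_seq: str = ALL_CRITERIA_SITE
    n_background: int = 3
    background_len: int = 400
    planted_offtargets: Tuple[PlantedOfftarget, ...] = ()
    seed: int = 0
    au_bias: float = 0.35  # per-base weight for A and for U
    #: surround each planted site with this many adenosines per side so the
    #: local MFE fold leaves the site unpaired (an accessible target site is
    #: part of what "all criteria satisfied" means); 0 disables
    accessible_flank: int = 25

    def __post_init__(self) -> None:
        L = len(self.site_seq)
        for pos in self.site_positions:
            if not 1 <= pos <= self.transcript_len - L + 1:
                raise ValueError(f"planted site at {pos} outside transcript bounds")
        for ot in self.planted_offtargets:
            if not 0 <= ot.record < self.n_background:
                raise ValueError(f"off-target record index {ot.record} out of range")
            if not 0 <= ot.mismatches <= L:
                raise ValueError(f"mismatch count {ot.mismatches} out of range")


@dataclass
class Fixtures:
    transcript: RnaStrand
    background: List[RnaStrand]
    manifest: Dict[str, object] = field(default_factory=dict)

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcript": outdir / "transcript.fasta",
            "background": outdir / "background.fasta",
            "manifest": outdir / "manifest.json",
        }
        write_fasta([self.transcript], paths["transcript"])
        write_fasta(self.background, paths["background"])
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2) + "\n")
        return paths


def _random_seq(rng: random.Random, n: int, au_bias: float) -> str:
    gc = (1.0 - 2 * au_bias) / 2
    weights = [au_bias, gc, gc, au_bias]  # A C G U
    return "".join(rng.choices(_BASES, weights=weights, k=n))


def _mutate(rng: random.Random, seq: str, n_sub: int) -> Tuple[str, List[int]]:
    """Apply exactly n_sub substitutions at distinct positions."""
    positions = sorted(rng.sample(range(len(seq)), n_sub))
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out), [p + 1 for p in positions]


def make_fixtures(spec: FixtureSpec) -> Fixtures:
    """Build transcript + background with planted features and a ground-truth
    manifest.  Fully determined by ``spec.seed``."""
    rng = random.Random(spec.seed)
    L = len(spec.site_seq)

    seq = list(_random_seq(rng, spec.transcript_len, spec.au_bias))
    for pos in spec.site_positions:
        if spec.accessible_flank:
            lo = max(0, pos - 1 - spec.accessible_flank)
            hi = min(spec.transcript_len, pos - 1 + L + spec.accessible_flank)
            seq[lo:hi] = "A" * (hi - lo)
        seq[pos - 1 : pos - 1 + L] = spec.site_seq
    transcript = RnaStrand("".join(seq), name="synthetic_transcript")

    background: List[RnaStrand] = []
    bg_seqs = [
        list(_random_seq(rng, spec.background_len, spec.au_bias))
        for _ in range(spec.n_background)
    ]
    planted: List[Dict[str, object]] = []
    for ot in spec.planted_offtargets:
        mutated, sub_positions = _mutate(rng, spec.site_seq, ot.mismatches)
        pos = ot.position
        if pos == -1:
            pos = (spec.background_len - L) // 2 + 1
        if not 1 <= pos <= spec.background_len - L + 1:
            raise ValueError(f"off-target plant position {pos} out of bounds")
        bg_seqs[ot.record][pos - 1 : pos - 1 + L] = mutated
        planted.append(
            {
                "record": f"background_{ot.record + 1}",
                "position": pos,
                "mismatches": ot.mismatches,
                "substituted_site_positions": sub_positions,
                "expected_identity_pct": round(100.0 * (L - ot.mismatches) / L, 2),
            }
        )
    for i, bs in enumerate(bg_seqs, start=1):
        background.append(RnaStrand("".join(bs), name=f"background_{i}"))

    manifest = {
        "seed": spec.seed,
        "transcript_id": transcript.name,
        "transcript_len": spec.transcript_len,
        "site_seq": spec.site_seq,
        "site_positions": list(spec.site_positions),
        "planted_offtargets": planted,
    }
    return Fixtures(transcript=transcript, background=background, manifest=manifest)
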