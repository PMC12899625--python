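"""End-to-end design pipeline: enumerate -> first-pass filter -> score -> rank.

The pipeline is a pure function of its inputs and configuration: identical
inputs produce byte-identical TSV reports.  Every threshold in force is
recorded in the run log and in the report's provenance header.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple, Union

import yaml

from .candidates import CandidateSet, enumerate_candidates, first_pass_filter
from .core import RnaStrand
from .scoring import (
    DEFAULT_SELECTION_THRESHOLD,
    ScoreCard,
    ScoringContext,
    cards_to_frame,
    rank_candidates,
    score_duplex,
)

logger = logging.getLogger("sirnakit")


@dataclass
class RunConfig:
    """Pipeline configuration; CLI flags override file values."""

    duplex_len: int = 21
    overhang: int = 2
    rules: Tuple[str, ...] = ()          # empty = no first-pass filter
    rule_mode: str = "union"
    valley_margin: float = 0.5
    fold_window: int = 80
    accessibility_threshold: float = 0.5
    offtarget_threshold_pct: float = 85.0
    selection_threshold: int = DEFAULT_SELECTION_THRESHOLD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rules" in raw:
            raw["rules"] = tuple(raw["rules"])
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def design_pipeline(
    transcript: RnaStrand,
    background: Optional[Sequence[RnaStrand]] = None,
    config: Optional[RunConfig] = None,
) -> Tuple[List[ScoreCard], "object"]:
    """Run the full design stack on one transcript.

    Returns the ranked score cards and a report DataFrame (one row per
    candidate, per-criterion point columns, provenance in ``df.attrs``).
    """
    cfg = config or RunConfig()
    logger.info(
        "design: transcript=%s len=%d rules=%s mode=%s thresholds: valley_margin=%.2f "
        "accessibility=%.2f offtarget=%.1f%% selection>%d",
        transcript.name, len(transcript), list(cfg.rules) or "none", cfg.rule_mode,
        cfg.valley_margin, cfg.accessibility_threshold, cfg.offtarget_threshold_pct,
        cfg.selection_threshold,
    )
    cands = enumerate_candidates(transcript, length=cfg.duplex_len, overhang=cfg.overhang)
    logger.info("enumerated %d candidates", len(cands))
    if cfg.rules:
        cands = first_pass_filter(cands, set(cfg.rules), mode=cfg.rule_mode)
        logger.info("first-pass filter retained %d candidates", len(cands))

    ctx = ScoringContext(
        transcript=transcript,
        background=background,
        target_id=transcript.name,
        valley_margin=cfg.valley_margin,
        fold_window=cfg.fold_window,
        accessibility_threshold=cfg.accessibility_threshold,
        offtarget_threshold_pct=cfg.offtarget_threshold_pct,
        selection_threshold=cfg.selection_threshold,
    )
    cards = [score_duplex(d, ctx) for d in cands.duplexes]
    ranked = rank_candidates(cards)
    df = cards_to_frame(ranked)
    df.attrs["config_digest"] = cfg.digest()
    n_sel = int(df["selectable"].sum()) if len(df) else 0
    logger.info("scored %d candidates; %d selectable (> %d points)",
                len(cards), n_sel, cfg.selection_threshold)
    return ranked, df


def report_tsv(df, config: Optional[RunConfig] = None) -> str:
    """Render the report DataFrame as TSV with a provenance comment header."""
    buf = io.StringIO()
    cfg = config or RunConfig()
    buf.write(f"# sirnakit design report; config sha256:{cfg.digest()}\n")
    buf.write(
        f"# criterion weights sum to {df.attrs.get('weight_sum', 16)}; "
        f"nominal maximum {df.attrs.get('nominal_max_points', 15)} points\n"
    )
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
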