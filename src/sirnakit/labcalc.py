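"""Laboratory support calculators.

* **Oligo mass** -- average (or monoisotopic) molecular weight of a modified
  oligonucleotide in the free-acid (H+) form: 5'-OH and 3'-OH termini,
  protonated phosphates.  Masses are accumulated as whole-molecule elemental
  formulas from IUPAC atomic weights rather than pre-rounded per-residue
  constants, so rounding never compounds across 21 residues.  A conjugate
  ligand (e.g. a triantennary GalNAc-linker) enters as a single configurable
  adduct mass.
* **Synthesis yield planner** -- total yield of a chained synthesis route as
  the product of per-stage efficiencies, with half-up integer percent
  rendering.
* **Relative expression (ddCq)** -- the standard qPCR quantification:
  dCt = Ct(target) - Ct(housekeeping) per replicate, ddCt = mean dCt of the
  experimental group minus mean dCt of the control group, fold change =
  2^(-ddCt).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .core import ModifiedOligo, parse_modified

# IUPAC 2021 standard atomic weights (conventional values)
ATOMIC_WEIGHTS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "F": 18.998,
    "S": 32.06,
}

MONOISOTOPIC_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "F": 18.998403,
    "S": 31.972071,
}

# Ribonucleoside molecular formulas (free nucleoside, 2'-OH)
_NUCLEOSIDE_FORMULAS: Dict[str, Dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},   # adenosine
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},   # guanosine
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},    # cytidine
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},    # uridine
    "T": {"C": 10, "H": 14, "N": 2, "O": 6},   # ribothymidine; deoxy via sugar 'd'
}

# Sugar chemistry deltas relative to the 2'-OH ribonucleoside
_SUGAR_DELTAS: Dict[str, Dict[str, int]] = {
    "r": {},
    "m": {"C": 1, "H": 2},              # 2'-O-methyl: +CH2
    "f": {"F": 1, "O": -1, "H": -1},    # 2'-fluoro: OH -> F
    "d": {"O": -1},                     # 2'-deoxy: -O
}

# Internucleotide phosphodiester bridge: +HPO3 then -H2O on condensation
_BRIDGE_DELTA: Dict[str, int] = {"P": 1, "O": 2, "H": -1}
# Phosphorothioate: one non-bridging O replaced by S
_PS_DELTA: Dict[str, int] = {"S": 1, "O": -1}


def _formula_mass(formula: Dict[str, int], weights: Dict[str, float]) -> float:
    return sum(n * weights[el] for el, n in formula.items())


@dataclass(frozen=True)
class MassTable:
    """Mass convention bundle: atomic weights + optional adduct constant.

    The per-residue constants of the usual desk tables (e.g. adenosine
    267.24, 2'-OMe +14.03, bridge +61.96) are exposed as derived values via
    :meth:`nucleoside_mass`, :meth:`sugar_delta` and the bridge/PS
    properties; the engine itself always sums elemental formulas.
    """

    monoisotopic: bool = False
    adduct_mass: float = 0.0   # e.g. conjugated ligand + linker, g/mol
    adduct_name: str = ""

    @property
    def weights(self) -> Dict[str, float]:
        return MONOISOTOPIC_MASSES if self.monoisotopic else ATOMIC_WEIGHTS

    def nucleoside_mass(self, base: str, sugar: str = "r") -> float:
        formula = Counter(_NUCLEOSIDE_FORMULAS[base])
        formula.update(_SUGAR_DELTAS[sugar])
        return _formula_mass(formula, self.weights)

    def sugar_delta(self, sugar: str) -> float:
        return _formula_mass(_SUGAR_DELTAS[sugar], self.weights)

    @property
    def bridge_mass(self) -> float:
        return _formula_mass(_BRIDGE_DELTA, self.weights)

    @property
    def ps_delta(self) -> float:
        return _formula_mass(_PS_DELTA, self.weights)


def oligo_formula(oligo: ModifiedOligo) -> Dict[str, int]:
    """Whole-molecule elemental formula, free-acid (H+) form."""
    formula: Counter = Counter()
    for res in oligo.residues:
        base = res.base
        sugar = res.sugar
        if base == "T" and sugar == "d":
            # thymidine = deoxyribothymidine
            formula.update(_NUCLEOSIDE_FORMULAS["T"])
            formula.update(_SUGAR_DELTAS["d"])
        else:
            formula.update(_NUCLEOSIDE_FORMULAS[base])
            formula.update(_SUGAR_DELTAS[sugar])
    n = len(oligo)
    for _ in range(n - 1):
        formula.update(_BRIDGE_DELTA)
    for res in oligo.residues:
        if res.linkage3 == "ps":
            formula.update(_PS_DELTA)
    return {el: cnt for el, cnt in formula.items() if cnt}


def oligo_mass(
    oligo: Union[ModifiedOligo, str],
    table: Optional[MassTable] = None,
) -> float:
    """Average molecular weight (g/mol) of a modified oligo, to 2 decimals.

    Accepts a :class:`ModifiedOligo` or a notation string.  Free-acid (H+)
    form: 5'-OH / 3'-OH termini, n-1 phosphodiester (or PS) bridges.  Any
    conjugate adduct configured on the table is added once.
    """
    if isinstance(oligo, str):
        oligo = parse_modified(oligo)
    table = table or MassTable()
    mass = _formula_mass(oligo_formula(oligo), table.weights) + table.adduct_mass
    return round(mass, 2)


# ---------------------------------------------------------------------------
# Synthesis yield planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YieldPlan:
    stages: Tuple[Tuple[str, float], ...]
    total: float

    def total_percent(self) -> str:
        """Integer percent, rounded half-up (25.6% -> \"26%\")."""
        pct = Decimal(str(self.total * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        return f"{pct}%"


def chain_yield(
    stages: Sequence[Union[Tuple[str, float], float]]
) -> YieldPlan:
    """Total yield of a multi-stage route = product of stage efficiencies.

    Each stage is ``(name, efficiency)`` or a bare efficiency in (0, 1].
    The total is permutation-invariant and never exceeds the weakest stage.
    """
    named: List[Tuple[str, float]] = []
    for i, stage in enumerate(stages, start=1):
        if isinstance(stage, (int, float)):
            name, eff = f"stage{i}", float(stage)
        else:
            name, eff = stage[0], float(stage[1])
        if not 0 < eff <= 1:
            raise ValueError(f"stage {name!r}: efficiency {eff} outside (0, 1]")
        named.append((name, eff))
    if not named:
        raise ValueError("no stages")
    total = 1.0
    for _, eff in named:
        total *= eff
    return YieldPlan(stages=tuple(named), total=total)


# ---------------------------------------------------------------------------
# Relative expression (ddCq)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    ct_target: float
    ct_housekeeping: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_housekeeping <= 0:
            raise ValueError("Ct values must be positive cycle numbers")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


def delta_delta_ct(
    experimental: Sequence[CtRecord], control: Sequence[CtRecord]
) -> float:
    """Mean dCt of the experimental group minus mean dCt of the control."""
    if not experimental or not control:
        raise ValueError("both groups must be non-empty")
    mean_exp = sum(r.delta_ct for r in experimental) / len(experimental)
    mean_ctl = sum(r.delta_ct for r in control) / len(control)
    return mean_exp - mean_ctl


def fold_change(
    experimental: Sequence[CtRecord], control: Sequence[CtRecord]
) -> float:
    """Relative expression 2^(-ddCt); 1.0 means no change, 0.5 a 2-fold drop."""
    return 2.0 ** (-delta_delta_ct(experimental, control))
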