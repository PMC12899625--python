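"""Target-site accessibility via minimum-free-energy secondary structure.

A simplified Zuker-style dynamic program over nested Watson-Crick
structures: stacking energies come from the bundled nearest-neighbor table,
hairpin/bulge/internal loops carry coarse size-dependent penalties, and
multiloops an affine cost.  GU wobbles and pseudoknots are not modeled.
The folder exists to answer one question -- what fraction of a candidate
target site is base-paired in the MFE structure of its local mRNA context
-- and an adapter hook allows delegating to an external folding engine.

Determinism: the traceback examines decompositions in a fixed order
(prefer leaving the 3' base unpaired, then pairings with smallest i, then
smallest j), so identical input always yields an identical dot-bracket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, List, Optional, Set, Tuple, Union

from .core import RnaStrand
from .thermo import NNParamSet, default_params

_RT = 0.616  # kcal/mol at 37 C
_JS_COEF = 1.75

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

_DEFAULT_LOOPS: Optional["LoopParams"] = None


@dataclass(frozen=True)
class LoopParams:
    hairpin: Dict[int, float]
    bulge: Dict[int, float]
    internal: Dict[int, float]
    ml_closing: float
    ml_branch: float
    ml_unpaired: float

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "LoopParams":
        tables: Dict[str, Dict] = {"hairpin": {}, "bulge": {}, "internal": {}, "multiloop": {}}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, size, val = line.split("\t")
            key = size if kind == "multiloop" else int(size)
            tables[kind][key] = float(val)
        return cls(
            hairpin=tables["hairpin"],
            bulge=tables["bulge"],
            internal=tables["internal"],
            ml_closing=tables["multiloop"]["closing"],
            ml_branch=tables["multiloop"]["branch"],
            ml_unpaired=tables["multiloop"]["unpaired"],
        )

    def _extrapolate(self, table: Dict[int, float], n: int) -> float:
        nmax = max(table)
        if n in table:
            return table[n]
        if n < min(table):
            raise ValueError(f"loop size {n} below tabulated minimum")
        return table[nmax] + _JS_COEF * _RT * math.log(n / nmax)

    def hairpin_penalty(self, n: int) -> float:
        return self._extrapolate(self.hairpin, n)

    def bulge_penalty(self, n: int) -> float:
        return self._extrapolate(self.bulge, n)

    def internal_penalty(self, n: int) -> float:
        return self._extrapolate(self.internal, n)


def default_loop_params() -> LoopParams:
    global _DEFAULT_LOOPS
    if _DEFAULT_LOOPS is None:
        ref = resources.files("sirnakit.data") / "loop_params.tsv"
        with resources.as_file(ref) as p:
            _DEFAULT_LOOPS = LoopParams.from_tsv(p)
    return _DEFAULT_LOOPS


@dataclass(frozen=True)
class FoldResult:
    window_seq: str
    structure: str  # dot-bracket, same length as window_seq
    mfe: float
    site_paired_fraction: float = 0.0

    def pairs(self) -> Set[Tuple[int, int]]:
        return set(_parse_dotbracket(self.structure))


def _parse_dotbracket(db: str) -> List[Tuple[int, int]]:
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return pairs


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _WC


_INF = float("inf")


class _Folder:
    """O(n^3) MFE dynamic program (interior loop size capped)."""

    def __init__(
        self,
        seq: str,
        min_hairpin: int,
        nn: NNParamSet,
        loops: LoopParams,
        max_interior: int = 30,
    ):
        self.s = seq
        self.n = len(seq)
        self.h = min_hairpin
        self.nn = nn
        self.lp = loops
        self.max_interior = max_interior
        n = self.n
        self.V = [[_INF] * n for _ in range(n)]
        self.WM = [[_INF] * n for _ in range(n)]
        self.W = [0.0] * (n + 1)

    def run(self) -> Tuple[float, str]:
        n = self.n
        # V and WM interleaved by span: V(i,j) at span s reads WM at spans < s
        for span in range(0, n):
            for i in range(n - span):
                j = i + span
                if span >= self.h + 1:
                    self._fill_V(i, j)
                self._fill_WM(i, j)
        W = self.W
        for j in range(1, n + 1):
            best = W[j - 1]
            for i in range(1, j + 1):
                v = self.V[i - 1][j - 1]
                if v < _INF:
                    best = min(best, W[i - 1] + v)
            W[j] = best
        structure = self._traceback()
        return W[n], structure

    # -- energy terms ------------------------------------------------------
    def _stack(self, i: int) -> float:
        return self.nn.stack(self.s[i : i + 2])

    def _loop_energy(self, i: int, j: int, k: int, l: int) -> float:
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            return self._stack(i)
        if n1 == 0 or n2 == 0:
            return self.lp.bulge_penalty(n1 + n2)
        return self.lp.internal_penalty(n1 + n2)

    # -- DP fills ----------------------------------------------------------
    def _fill_V(self, i: int, j: int) -> None:
        s = self.s
        if not can_pair(s[i], s[j]):
            return
        if j - i - 1 < self.h:
            return
        best = self.lp.hairpin_penalty(j - i - 1)
        # interior decompositions (includes stacks and bulges)
        for k in range(i + 1, j):
            if k - i - 1 > self.max_interior:
                break
            for l in range(max(k + self.h + 1, j - self.max_interior + (k - i - 1)), j):
                v = self.V[k][l]
                if v < _INF:
                    cand = v + self._loop_energy(i, j, k, l)
                    if cand < best:
                        best = cand
        # multiloop: at least two branches inside
        for k in range(i + 1, j - 1):
            a, b = self.WM[i + 1][k], self.WM[k + 1][j - 1]
            if a < _INF and b < _INF:
                cand = self.lp.ml_closing + self.lp.ml_branch + a + b
                if cand < best:
                    best = cand
        self.V[i][j] = best

    def _fill_WM(self, i: int, j: int) -> None:
        """WM(i,j): min multiloop-interior energy with >= 1 helix branch."""
        lp = self.lp
        best = _INF
        v = self.V[i][j]
        if v < _INF:
            best = v + lp.ml_branch
        if i + 1 <= j:
            a = self.WM[i + 1][j]
            if a < _INF:
                best = min(best, a + lp.ml_unpaired)
            a = self.WM[i][j - 1]
            if a < _INF:
                best = min(best, a + lp.ml_unpaired)
            for k in range(i + 1, j + 1):
                a, b = self.WM[i][k - 1], self.WM[k][j]
                if a < _INF and b < _INF:
                    best = min(best, a + b)
        self.WM[i][j] = best

    # -- traceback ---------------------------------------------------------
    def _traceback(self) -> str:
        db = ["."] * self.n
        eps = 1e-9

        def trace_V(i: int, j: int) -> None:
            db[i], db[j] = "(", ")"
            target = self.V[i][j]
            if j - i - 1 >= self.h and abs(
                self.lp.hairpin_penalty(j - i - 1) - target
            ) < eps:
                return
            for k in range(i + 1, j):
                if k - i - 1 > self.max_interior:
                    break
                for l in range(k + self.h + 1, j):
                    if j - l - 1 > self.max_interior:
                        continue
                    v = self.V[k][l]
                    if v < _INF and abs(v + self._loop_energy(i, j, k, l) - target) < eps:
                        trace_V(k, l)
                        return
            for k in range(i + 1, j - 1):
                a, b = self.WM[i + 1][k], self.WM[k + 1][j - 1]
                if a < _INF and b < _INF and abs(
                    self.lp.ml_closing + self.lp.ml_branch + a + b - target
                ) < eps:
                    trace_WM(i + 1, k)
                    trace_WM(k + 1, j - 1)
                    return
            raise AssertionError("traceback failed in V")

        def trace_WM(i: int, j: int) -> None:
            target = self.WM[i][j]
            if target >= _INF:
                raise AssertionError("traceback into infeasible WM")
            v = self.V[i][j]
            if v < _INF and abs(v + self.lp.ml_branch - target) < eps:
                trace_V(i, j)
                return
            if i + 1 <= j:
                if abs(self.WM[i + 1][j] + self.lp.ml_unpaired - target) < eps:
                    trace_WM(i + 1, j)
                    return
                if abs(self.WM[i][j - 1] + self.lp.ml_unpaired - target) < eps:
                    trace_WM(i, j - 1)
                    return
                for k in range(i + 1, j + 1):
                    a, b = self.WM[i][k - 1], self.WM[k][j]
                    if a < _INF and b < _INF and abs(a + b - target) < eps:
                        trace_WM(i, k - 1)
                        trace_WM(k, j)
                        return
            raise AssertionError("traceback failed in WM")

        def trace_W(j: int) -> None:
            # j is 1-based prefix length
            while j > 0:
                if abs(self.W[j] - self.W[j - 1]) < eps:
                    j -= 1
                    continue
                found = False
                for i in range(1, j + 1):
                    v = self.V[i - 1][j - 1]
                    if v < _INF and abs(self.W[i - 1] + v - self.W[j]) < eps:
                        trace_V(i - 1, j - 1)
                        j = i - 1
                        found = True
                        break
                if not found:
                    raise AssertionError("traceback failed in W")

        trace_W(self.n)
        return "".join(db)


def energy_of_structure(
    seq: str,
    pairs: Set[Tuple[int, int]],
    min_hairpin: int = 3,
    nn: Optional[NNParamSet] = None,
    loops: Optional[LoopParams] = None,
) -> float:
    """Free energy of an explicit nested structure under the same model.

    Direct loop-decomposition evaluation (no dynamic programming): each pair
    is classified by its directly enclosed pairs as closing a hairpin,
    stack/bulge/internal loop, or multiloop.  Used as the independent
    evaluator in exhaustive-enumeration cross-checks.
    """
    nn = nn or default_params()
    loops = loops or default_loop_params()
    seq = seq.upper().replace("T", "U")
    plist = sorted(pairs)
    for (i, j) in plist:
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"non-WC pair ({i},{j})")
        if j - i - 1 < min_hairpin:
            raise ValueError(f"pair ({i},{j}) violates min hairpin {min_hairpin}")

    def children_of(i: int, j: int) -> List[Tuple[int, int]]:
        # outermost pairs strictly inside (i,j)
        inside = [(k, l) for (k, l) in plist if i < k < l < j]
        return sorted(
            p
            for p in inside
            if not any(q != p and q[0] < p[0] and p[1] < q[1] for q in inside)
        )

    total = 0.0
    for (i, j) in plist:
        kids = children_of(i, j)
        if not kids:
            total += loops.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += nn.stack(seq[i : i + 2])
            elif n1 == 0 or n2 == 0:
                total += loops.bulge_penalty(n1 + n2)
            else:
                total += loops.internal_penalty(n1 + n2)
        else:
            enclosed = sum(l - k + 1 for (k, l) in kids)
            unpaired = (j - i - 1) - enclosed
            total += (
                loops.ml_closing
                + loops.ml_branch * (1 + len(kids))
                + loops.ml_unpaired * unpaired
            )
    return total


def fold_window(
    seq: Union[RnaStrand, str],
    min_hairpin: int = 3,
    max_len: int = 200,
    nn: Optional[NNParamSet] = None,
    loops: Optional[LoopParams] = None,
    engine: Optional[Callable[[str], Tuple[str, float]]] = None,
) -> FoldResult:
    """MFE fold of a sequence window; deterministic dot-bracket output.

    ``engine`` is an adapter hook: a callable mapping a sequence to a
    ``(dot_bracket, mfe)`` pair from an external folding program; when
    given, it replaces the built-in dynamic program.  Windows longer than
    ``max_len`` are rejected (use an external engine for those).
    """
    s = seq.seq if isinstance(seq, RnaStrand) else seq.upper().replace("T", "U")
    if not 1 <= len(s) <= max_len:
        raise ValueError(
            f"window length {len(s)} outside 1..{max_len}; supply an external "
            "engine for longer windows"
        )
    if engine is not None:
        db, mfe = engine(s)
        if len(db) != len(s):
            raise ValueError("external engine returned structure of wrong length")
        return FoldResult(window_seq=s, structure=db, mfe=mfe)
    if len(s) < min_hairpin + 2:
        return FoldResult(window_seq=s, structure="." * len(s), mfe=0.0)
    folder = _Folder(s, min_hairpin, nn or default_params(), loops or default_loop_params())
    mfe, db = folder.run()
    return FoldResult(window_seq=s, structure=db, mfe=mfe)


def accessibility_criterion(
    transcript: RnaStrand,
    target_start: int,
    site_len: int = 21,
    window: int = 80,
    threshold: float = 0.5,
    **fold_kwargs,
) -> bool:
    """True iff <= ``threshold`` of the target site is paired in the MFE fold.

    The folding window of ``window`` nt is centered on the site and clamped
    at the transcript ends.
    """
    L = len(transcript)
    site_end = target_start + site_len - 1  # 1-based inclusive
    if target_start < 1 or site_end > L:
        raise ValueError(
            f"site {target_start}..{site_end} outside transcript 1..{L}"
        )
    center = (target_start + site_end) // 2
    w_start = max(1, center - window // 2)
    w_end = min(L, w_start + window - 1)
    w_start = max(1, w_end - window + 1)
    sub = transcript.seq[w_start - 1 : w_end]
    result = fold_window(sub, **fold_kwargs)
    paired = {i for pair in _parse_dotbracket(result.structure) for i in pair}
    site_idx = range(target_start - w_start, site_end - w_start + 1)
    frac = sum(i in paired for i in site_idx) / len(site_idx)
    return frac <= threshold


def site_fold(
    transcript: RnaStrand,
    target_start: int,
    site_len: int = 21,
    window: int = 80,
    **fold_kwargs,
) -> FoldResult:
    """Fold the window around a site and report its paired fraction."""
    L = len(transcript)
    site_end = target_start + site_len - 1
    if target_start < 1 or site_end > L:
        raise ValueError(f"site {target_start}..{site_end} outside transcript 1..{L}")
    center = (target_start + site_end) // 2
    w_start = max(1, center - window // 2)
    w_end = min(L, w_start + window - 1)
    w_start = max(1, w_end - window + 1)
    sub = transcript.seq[w_start - 1 : w_end]
    result = fold_window(sub, **fold_kwargs)
    paired = {i for pair in _parse_dotbracket(result.structure) for i in pair}
    site_idx = range(target_start - w_start, site_end - w_start + 1)
    frac = sum(i in paired for i in site_idx) / len(site_idx)
    return FoldResult(
        window_seq=result.window_seq,
        structure=result.structure,
        mfe=result.mfe,
        site_paired_fraction=frac,
    )
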