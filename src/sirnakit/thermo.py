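"""Nearest-neighbor duplex thermodynamics.

Per-step free-energy profiles for perfectly complementary duplexes, the
"energy valley" detector used by the scoring engine (a locally less stable
stretch in sense positions 9-14 favoring RISC-mediated cleavage), and the
5'/3' end-energy asymmetry diagnostic that guides guide-strand selection
and the modification heuristics.

The bundled parameter table is the Watson-Crick RNA/RNA dG37 set of
Xia et al. (1998); it is a data fixture and can be swapped for any table
with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .core import RnaStrand, SirnaDuplex, reverse_complement

_DEFAULT_PARAMS: Optional["NNParamSet"] = None


@dataclass(frozen=True)
class NNParamSet:
    """16 WC stack dG37 values plus initiation and terminal-AU terms."""

    stacks: dict  # dinucleotide -> kcal/mol
    init: float
    terminal_au: float

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "NNParamSet":
        stacks = {}
        init = terminal_au = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")
            if key == "init":
                init = float(val)
            elif key == "terminal_au":
                terminal_au = float(val)
            else:
                stacks[key] = float(val)
        if init is None or terminal_au is None or len(stacks) != 16:
            raise ValueError(f"incomplete nearest-neighbor table: {path}")
        return cls(stacks=stacks, init=init, terminal_au=terminal_au)

    def stack(self, dinuc: str) -> float:
        key = dinuc.upper().replace("T", "U")
        try:
            return self.stacks[key]
        except KeyError:
            raise KeyError(f"no stack parameter for dinucleotide {dinuc!r}") from None


def default_params() -> NNParamSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        ref = resources.files("sirnakit.data") / "nn_rna_wc_dg37.tsv"
        with resources.as_file(ref) as p:
            _DEFAULT_PARAMS = NNParamSet.from_tsv(p)
    return _DEFAULT_PARAMS


@dataclass(frozen=True)
class ThermoProfile:
    """Per-step dG profile of a perfect duplex.

    ``steps[i]`` is ``(position, dg)`` where position is the 1-based index of
    the 5' base of dinucleotide step ``position`` on the profiled strand;
    there are ``length - 1`` steps.  ``total_dg`` includes the initiation
    term and terminal-AU penalties.
    """

    steps: Tuple[Tuple[int, float], ...]
    total_dg: float
    end5_dg: float
    end3_dg: float

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def step_dg(self, position: int) -> float:
        if not 1 <= position <= self.n_steps:
            raise IndexError(f"step {position} outside 1..{self.n_steps}")
        return self.steps[position - 1][1]


def profile_for_sequence(
    seq: str, params: Optional[NNParamSet] = None, end_window: int = 4
) -> ThermoProfile:
    """Profile for a sequence assumed paired to its perfect complement."""
    params = params or default_params()
    seq = seq.upper().replace("T", "U")
    if len(seq) < 2:
        raise ValueError("profile needs at least 2 nt")
    steps = tuple(
        (i + 1, params.stack(seq[i : i + 2])) for i in range(len(seq) - 1)
    )
    total = sum(dg for _, dg in steps) + params.init
    for terminal in (seq[0], seq[-1]):
        if terminal in "AU":
            total += params.terminal_au
    k = min(end_window, len(steps))
    end5 = sum(dg for _, dg in steps[:k]) / k
    end3 = sum(dg for _, dg in steps[-k:]) / k
    return ThermoProfile(steps=steps, total_dg=total, end5_dg=end5, end3_dg=end3)


def nn_profile(
    duplex: SirnaDuplex,
    params: Optional[NNParamSet] = None,
    strand: str = "sense",
) -> ThermoProfile:
    """Per-step dG profile of the duplex core (overhangs excluded).

    Step i is the stack of dinucleotide i of the chosen strand's core paired
    to its complement.  The duplex must be perfectly complementary over the
    core; this is enforced by :class:`SirnaDuplex` itself.
    """
    if strand == "sense":
        core = duplex.sense_core
    elif strand == "antisense":
        core = duplex.antisense_core
    else:
        raise ValueError(f"strand must be 'sense' or 'antisense', got {strand!r}")
    return profile_for_sequence(core, params=params)


def energy_valley(
    profile: ThermoProfile,
    window: Tuple[int, int] = (9, 14),
    margin: float = 0.5,
    statistic: str = "mean_vs_rest",
) -> bool:
    """Detect a local low-stability stretch over strand positions ``window``.

    A window covering positions a..b maps to dinucleotide steps a..b-1 (the
    steps whose both bases lie inside the window).  ``mean_vs_rest`` (the
    default) is true iff the mean step dG inside the window is less negative
    than the mean over all remaining steps by at least ``margin`` kcal/mol.
    ``min_window`` compares the single least stable step inside vs outside.
    Monotone decreasing in ``margin``.
    """
    a, b = window
    lo, hi = a, b - 1  # steps fully inside the positional window
    if lo < 1 or hi > profile.n_steps or lo > hi:
        raise ValueError(f"window {window} maps to steps outside 1..{profile.n_steps}")
    inside = [dg for pos, dg in profile.steps if lo <= pos <= hi]
    outside = [dg for pos, dg in profile.steps if not lo <= pos <= hi]
    if not outside:
        raise ValueError("window covers the whole profile; no reference steps")
    if statistic == "mean_vs_rest":
        stat = sum(inside) / len(inside) - sum(outside) / len(outside)
    elif statistic == "min_window":
        stat = max(inside) - max(outside)
    else:
        raise ValueError(f"unknown valley statistic {statistic!r}")
    return stat >= margin


def end_differential(profile: ThermoProfile, k: int = 4) -> float:
    """(mean dG of first k steps) - (mean dG of last k steps).

    Computed on whichever strand the profile was built for; on an antisense
    profile a positive value marks the favorable asymmetry (less stable 5',
    more stable 3') that biases RISC toward loading the guide strand.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if profile.n_steps < 2 * k:
        raise ValueError(f"profile with {profile.n_steps} steps too short for k={k}")
    first = [dg for _, dg in profile.steps[:k]]
    last = [dg for _, dg in profile.steps[-k:]]
    return sum(first) / k - sum(last) / k


def step_differential(profile: ThermoProfile, i: int = 10, j: int = 11) -> float:
    """Absolute dG difference between two steps (default steps 10 and 11).

    The 10-11 differential on the antisense strand is the asymmetry feature
    shared by the most active designs.
    """
    return abs(profile.step_dg(i) - profile.step_dg(j))
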