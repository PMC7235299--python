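"""Nearest-neighbor thermodynamic scoring of DNA duplexes and hairpins.

This module is the package's secondary-structure assessor: candidate
hairpins are accepted only if their intended stem is the dominant
self-structure.  Free energies use the unified oligonucleotide
nearest-neighbor parameter set (37 degC, 1 M Na+) shipped as versioned
package data; ``dG37 = dH - T*dS`` with T = 310.15 K.  Salt correction
is deliberately out of scope: all candidates are compared under the
same reference condition, so only relative stabilities matter.

Partition functions are not computed.  ``fold_check`` instead enumerates
every alternative internal complementary run and requires the intended
stem to beat the best alternative by a free-energy margin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING

from .seqcore import normalize, reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .hairpins import HairpinSpec

__all__ = [
    "NNParameterSet",
    "load_default_parameters",
    "duplex_dg37",
    "hairpin_dg37",
    "FoldReport",
    "fold_check",
    "TooShortError",
    "GeometryError",
]

T_KELVIN = 310.15
_R = 0.0019872  # kcal/(mol*K)


class TooShortError(ValueError):
    """Sequence too short for a nearest-neighbor sum."""


class GeometryError(ValueError):
    """Hairpin geometry infeasible (e.g. loop shorter than 3 nt)."""


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor parameter table.

    ``stack_dH``/``stack_dS`` hold the 10 unique Watson-Crick
    dinucleotide stacks; the other 6 dinucleotides are looked up via
    their reverse complement.  Hairpin-loop penalties are dG37 values by
    loop size, with a logarithmic extrapolation beyond the largest
    tabulated size.
    """

    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    init_dH: float
    init_dS: float
    terminal_AT_dH: float
    terminal_AT_dS: float
    hairpin_loop_dG37: dict[int, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG"}
        missing = required - set(self.stack_dH) | required - set(self.stack_dS)
        if missing:
            raise ValueError(f"incomplete stack table, missing {sorted(missing)}")
        sizes = sorted(self.hairpin_loop_dG37)
        if sizes[0] > 3:
            raise ValueError("hairpin loop table must start at size 3")
        imin = min(range(len(sizes)), key=lambda i: self.hairpin_loop_dG37[sizes[i]])
        tail = [self.hairpin_loop_dG37[n] for n in sizes[imin:]]
        if any(b < a for a, b in zip(tail, tail[1:])):
            raise ValueError("loop penalties must be non-decreasing beyond their minimum")

    def stack_dg37(self, dinuc: str) -> float:
        """dG37 of one WC stack, looked up directly or via reverse complement."""
        key = dinuc if dinuc in self.stack_dH else reverse_complement(dinuc)
        return self.stack_dH[key] - T_KELVIN * self.stack_dS[key] / 1000.0

    def loop_penalty(self, size: int) -> float:
        """Hairpin-loop dG37 penalty for a loop of ``size`` nt."""
        if size < 3:
            raise GeometryError(f"hairpin loop of {size} nt is sterically infeasible")
        if size in self.hairpin_loop_dG37:
            return self.hairpin_loop_dG37[size]
        nmax = max(self.hairpin_loop_dG37)
        return self.hairpin_loop_dG37[nmax] + 1.75 * _R * T_KELVIN * math.log(size / nmax)


def load_default_parameters() -> NNParameterSet:
    """Load the packaged unified DNA parameter set (37 degC, 1 M Na+)."""
    raw = json.loads(
        resources.files("shorthcr.data").joinpath("nn_unified_dna.json").read_text()
    )
    return NNParameterSet(
        stack_dH=raw["stack_dH"],
        stack_dS=raw["stack_dS"],
        init_dH=raw["init_dH"],
        init_dS=raw["init_dS"],
        terminal_AT_dH=raw["terminal_AT_dH"],
        terminal_AT_dS=raw["terminal_AT_dS"],
        hairpin_loop_dG37={int(k): v for k, v in raw["hairpin_loop_dG37"].items()},
        metadata={
            k: raw[k]
            for k in ("name", "version", "temperature_K", "conditions", "source", "units")
        },
    )


def _stack_sum(s: str, params: NNParameterSet) -> tuple[float, float]:
    """(dH, dS) summed over the nearest-neighbor stacks of ``s``."""
    dh = ds = 0.0
    for i in range(len(s) - 1):
        d = s[i : i + 2]
        key = d if d in params.stack_dH else reverse_complement(d)
        dh += params.stack_dH[key]
        ds += params.stack_dS[key]
    return dh, ds


def duplex_dg37(s: str, params: NNParameterSet | None = None) -> float:
    """dG37 (kcal/mol) of ``s`` paired with its perfect complement.

    Bimolecular initiation plus stack terms plus terminal A:T penalties,
    evaluated as ``dH - T*dS``.  More negative means more stable; a
    hairpin stem needs to be much less stable than the long product
    duplex for the chain reaction to run forward.
    """
    params = params or load_default_parameters()
    s = normalize(s)
    if len(s) < 2:
        raise TooShortError("need at least 2 nt for a nearest-neighbor duplex")
    dh, ds = _stack_sum(s, params)
    dh += params.init_dH
    ds += params.init_dS
    for end in (s[0], s[-1]):
        if end in "AT":
            dh += params.terminal_AT_dH
            ds += params.terminal_AT_dS
    return dh - T_KELVIN * ds / 1000.0


def _stem_loop_dg37(stem: str, loop_size: int, params: NNParameterSet) -> float:
    """Unimolecular hairpin dG37: stem stacks (no initiation) + loop penalty."""
    dh, ds = _stack_sum(stem, params)
    return (dh - T_KELVIN * ds / 1000.0) + params.loop_penalty(loop_size)


def hairpin_dg37(h: "HairpinSpec", params: NNParameterSet | None = None) -> float:
    """dG37 (kcal/mol) of a hairpin's intended stem-loop structure.

    The stem duplex contributes its stack terms (no bimolecular
    initiation for a unimolecular fold); the loop contributes a
    size-dependent penalty.
    """
    params = params or load_default_parameters()
    stem = normalize(h.stem)
    if len(stem) < 2:
        raise TooShortError("stem must be at least 2 nt")
    if len(h.loop) < 3:
        raise GeometryError("loop must be at least 3 nt")
    return _stem_loop_dg37(stem, len(h.loop), params)


@dataclass(frozen=True)
class FoldReport:
    """Outcome of a secondary-structure check on one hairpin strand."""

    passed: bool
    intended_dg37: float
    best_alternative_dg37: float | None
    margin: float
    n_alternatives: int
    reason: str

    def __bool__(self) -> bool:
        return self.passed


def _complementary_runs(s: str, min_len: int = 4, min_loop: int = 3):
    """Yield (i, j, L): s[i:i+L] pairs s[j:j+L] as a stem with loop >= min_loop.

    Pairing register: position i+k pairs with j+L-1-k.  Enumeration is
    exhaustive over all starts and lengths (sequences here are <= ~50 nt).
    """
    n = len(s)
    for i in range(n - 2 * min_len - min_loop + 1):
        for j in range(i + min_len + min_loop, n - min_len + 1):
            lmax = min(n - j, j - i - min_loop)
            for length in range(min_len, lmax + 1):
                if s[j : j + length] == reverse_complement(s[i : i + length]):
                    yield i, j, length


def fold_check_coords(
    full: str,
    stem5_start: int,
    stem3_start: int,
    stem_len: int,
    params: NNParameterSet | None = None,
    margin: float = 2.0,
    min_run: int = 4,
) -> FoldReport:
    """Check that the stem pairing (stem5, stem3) dominates all alternatives.

    Enumerates every internal complementary run of >= ``min_run`` nt,
    drops runs whose base pairs are a subset of the intended stem's
    pairs, and passes iff the intended structure is lower in free energy
    than the best remaining alternative by at least ``margin`` kcal/mol.
    """
    params = params or load_default_parameters()
    full = normalize(full)
    loop_size = stem3_start - (stem5_start + stem_len)
    if loop_size < 3:
        raise GeometryError("intended loop shorter than 3 nt")
    intended_pairs = {
        (stem5_start + k, stem3_start + stem_len - 1 - k) for k in range(stem_len)
    }
    intended_dg = _stem_loop_dg37(full[stem5_start : stem5_start + stem_len], loop_size, params)

    best_alt: float | None = None
    n_alt = 0
    for i, j, length in _complementary_runs(full, min_len=min_run):
        pairs = {(i + k, j + length - 1 - k) for k in range(length)}
        if pairs <= intended_pairs:
            continue  # the intended stem or a sub-helix of it
        n_alt += 1
        dg = _stem_loop_dg37(full[i : i + length], j - (i + length), params)
        if best_alt is None or dg < best_alt:
            best_alt = dg

    if best_alt is None:
        return FoldReport(True, intended_dg, None, margin, 0, "no alternative structure")
    ok = intended_dg + margin <= best_alt
    reason = (
        "intended stem dominates"
        if ok
        else f"alternative structure within {margin} kcal/mol of intended stem"
    )
    return FoldReport(ok, intended_dg, best_alt, margin, n_alt, reason)


def fold_check(
    full_hairpin: str,
    intended: "HairpinSpec",
    params: NNParameterSet | None = None,
    margin: float = 2.0,
) -> FoldReport:
    """Secondary-structure check for an H1-layout hairpin (toehold-stem-loop-stem').

    Raises
    ------
    ValueError
        If ``full_hairpin`` is not the concatenation the spec defines.
    """
    full = normalize(full_hairpin)
    expected = (
        normalize(intended.toehold)
        + normalize(intended.stem)
        + normalize(intended.loop)
        + reverse_complement(intended.stem)
    )
    if full != expected:
        raise ValueError("sequence does not match the domain decomposition it claims")
    la, lb, lc = len(intended.toehold), len(intended.stem), len(intended.loop)
    return fold_check_coords(full, la, la + lb + lc, lb, params, margin)
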