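"""Domain-level HCR cascade verification and stochastic polymer growth.

``verify_cascade`` checks, by exact string complementarity on domain
slices, the five relations that make the chain reaction run:

  1. initiator is the reverse complement of H1's toehold+stem (a, b)
  2. H2's loop is complementary to H1's toehold (a)
  3. H2's toehold is complementary to H1's loop (c)
  4. H2's two stem copies are mutually complementary
  5. the strand H2 exposes when opened equals the initiator

``simulate_polymerization`` grows polymers under a well-mixed,
irreversible, uniform-event model: every unbound initiator and every
polymer end whose next hairpin species is still free is one feasible
event, and one is chosen uniformly at random per step.  The model is
structural, not kinetic — no rate constants are published for these
hairpins — so it reproduces stoichiometry (conservation, alternation,
mean degree of polymerization), not reaction time courses.

The module also hosts the arithmetic the amplification and cost claims
rest on: a polymer of ``dp`` hairpins of length L nt is a nicked duplex
of dp*L/2 bp, and per-mole oligo synthesis cost scales with the square
of oligo length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .seqcore import reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .hairpins import HairpinSpec

__all__ = [
    "CascadeReport",
    "verify_cascade",
    "ReactionPool",
    "PolymerEnsemble",
    "simulate_polymerization",
    "polymer_duplex_length",
    "fold_amplification",
    "synthesis_cost_ratio",
]

RELATIONS = (
    "initiator_vs_h1_toehold_stem",
    "h2_loop_vs_h1_toehold",
    "h2_toehold_vs_h1_loop",
    "h2_stem_self_pairing",
    "h2_exposed_vs_initiator",
)


@dataclass(frozen=True)
class CascadeReport:
    """Pass/fail for each of the five cascade domain relations."""

    results: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.results.values())

    @property
    def first_failure(self) -> str | None:
        for name in RELATIONS:
            if not self.results[name]:
                return name
        return None

    def __bool__(self) -> bool:
        return self.passed


def verify_cascade(h1: str, h2: str, initiator: str, spec: "HairpinSpec") -> CascadeReport:
    """Check the five domain relations of the H1/H2/initiator cascade.

    ``spec`` supplies the domain lengths used to slice ``h1`` and
    ``h2``; the sequences themselves are what is verified.
    """
    la, lb, lc = len(spec.toehold), len(spec.stem), len(spec.loop)
    if len(h1) != la + 2 * lb + lc or len(h2) != len(h1):
        raise ValueError("sequence lengths inconsistent with the domain geometry")
    if len(initiator) != la + lb:
        raise ValueError("initiator length must equal toehold + stem")

    a = h1[:la]
    c = h1[la + lb : la + lb + lc]
    h2_stem5 = h2[:lb]
    h2_loop = h2[lb : lb + la]
    h2_stem3 = h2[lb + la : lb + la + lb]
    h2_toehold = h2[lb + la + lb :]

    results = {
        RELATIONS[0]: initiator == reverse_complement(h1[: la + lb]),
        RELATIONS[1]: h2_loop == reverse_complement(a),
        RELATIONS[2]: h2_toehold == reverse_complement(c),
        RELATIONS[3]: h2_stem5 == reverse_complement(h2_stem3),
        RELATIONS[4]: h2[: la + lb] == initiator,
    }
    return CascadeReport(results)


@dataclass
class ReactionPool:
    """Molecule counts for one simulated HCR reaction.

    The gel experiments the model mirrors mixed hairpins at a constant
    concentration with initiator:hairpin ratios of 0, 1/200, 1/50 and
    1/10; ``from_ratio`` builds those presets.
    """

    n_h1: int
    n_h2: int
    n_init: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_h1, self.n_h2, self.n_init) < 0:
            raise ValueError("molecule counts must be non-negative")

    @classmethod
    def from_ratio(cls, n_hairpins: int, ratio: float, seed: int = 0) -> "ReactionPool":
        """Equal H1/H2 counts with ``n_init = round(ratio * n_hairpins)``."""
        if ratio < 0:
            raise ValueError("ratio must be non-negative")
        return cls(n_hairpins, n_hairpins, round(ratio * n_hairpins), seed)


@dataclass
class PolymerEnsemble:
    """Polymer size distribution produced by one simulation run."""

    sizes: list[int]
    hairpin_len_nt: int
    h1_consumed: int
    h2_consumed: int
    events: list[tuple[int, str]] = field(repr=False, default_factory=list)
    mass_trajectory: list[int] = field(repr=False, default_factory=list)

    @property
    def n_polymers(self) -> int:
        return len(self.sizes)

    @property
    def total_consumed(self) -> int:
        return self.h1_consumed + self.h2_consumed

    @property
    def total_nt(self) -> int:
        return self.total_consumed * self.hairpin_len_nt

    @property
    def mean_dp(self) -> float:
        return float(np.mean(self.sizes)) if self.sizes else 0.0

    def duplex_bp(self) -> list[float]:
        return [polymer_duplex_length(dp, self.hairpin_len_nt) for dp in self.sizes]


def simulate_polymerization(
    pool: ReactionPool,
    max_steps: int | None = None,
    seed: int | None = None,
    hairpin_len_nt: int = 42,
) -> PolymerEnsemble:
    """Grow polymers until no feasible event remains (or ``max_steps``).

    Events: an unbound initiator opens a free H1, nucleating a polymer
    of dp=1; a polymer whose next expected species (strict H1/H2
    alternation) is still free incorporates one copy.  Each step picks
    one feasible event uniformly at random.  Deterministic for a fixed
    seed; ``seed=None`` falls back to ``pool.seed``.
    """
    rng = np.random.default_rng(pool.seed if seed is None else seed)
    free_h1, free_h2, free_init = pool.n_h1, pool.n_h2, pool.n_init
    dps: list[int] = []
    events: list[tuple[int, str]] = []
    mass: list[int] = []
    consumed_h1 = consumed_h2 = 0
    step = 0
    while max_steps is None or step < max_steps:
        feasible: list[int] = []  # -1 encodes nucleation; >=0 a polymer index
        if free_init > 0 and free_h1 > 0:
            feasible.extend([-1] * free_init)
        for idx, dp in enumerate(dps):
            wants_h2 = dp % 2 == 1  # polymers start with H1
            if (wants_h2 and free_h2 > 0) or (not wants_h2 and free_h1 > 0):
                feasible.append(idx)
        if not feasible:
            break
        choice = feasible[int(rng.integers(0, len(feasible)))]
        if choice == -1:
            free_init -= 1
            free_h1 -= 1
            consumed_h1 += 1
            dps.append(1)
            events.append((len(dps) - 1, "H1"))
        else:
            if dps[choice] % 2 == 1:
                free_h2 -= 1
                consumed_h2 += 1
                events.append((choice, "H2"))
            else:
                free_h1 -= 1
                consumed_h1 += 1
                events.append((choice, "H1"))
            dps[choice] += 1
        step += 1
        mass.append(consumed_h1 + consumed_h2)
    return PolymerEnsemble(dps, hairpin_len_nt, consumed_h1, consumed_h2, events, mass)


def polymer_duplex_length(dp: int, hairpin_len_nt: int) -> float:
    """Nicked-duplex length in bp of a polymer of ``dp`` hairpins.

    Each incorporated hairpin contributes its full length as single
    strand; two strands make one duplex, hence dp * L / 2 bp.  477
    hairpins of 42 nt exceed 10 kb.
    """
    if dp < 1:
        raise ValueError("dp must be >= 1")
    if hairpin_len_nt < 1:
        raise ValueError("hairpin length must be positive")
    return dp * hairpin_len_nt / 2


def fold_amplification(target_duplex_bp: int, hairpin_len_nt: int) -> int:
    """Smallest dp whose nicked duplex reaches ``target_duplex_bp``.

    ceil(2 * target / hairpin_len); for a 10 kb product from 42-nt
    hairpins this is 477, i.e. at least ~400-fold amplification per
    initiation event.
    """
    if target_duplex_bp <= 0 or hairpin_len_nt <= 0:
        raise ValueError("inputs must be positive")
    return math.ceil(2 * target_duplex_bp / hairpin_len_nt)


def synthesis_cost_ratio(len_new: int, len_old: int) -> float:
    """Fractional per-mole synthesis cost saving under a quadratic cost model.

    1 - (len_new / len_old)^2: shortening hairpins from 72 to 42 nt
    saves ~66% because failed couplings compound with oligo length.
    """
    if len_new <= 0 or len_old <= 0:
        raise ValueError("lengths must be positive")
    return 1.0 - (len_new**2) / (len_old**2)
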