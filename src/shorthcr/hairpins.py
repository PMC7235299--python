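"""Short-hairpin amplifier design: domain algebra, constraints, seeded search.

A hairpin pair (H1, H2) is written in a three-domain algebra: toehold
``a``, stem ``b``, loop ``c`` (primes denote reverse complements):

    H1 = a  + b  + c  + b'        (42 nt for the default 9/12/9 geometry)
    H2 = b' + a' + b  + c'
    initiator = (a + b)' = b' + a'   (21 nt)

The initiator invades H1 through its toehold; the opened H1 tail
(c, b') invades H2 through H2's toehold (c', b); the opened H2 tail
(b', a') is exactly the initiator again, so polymerization chains.

Composition rules enforced by the designer (all on the written strand):
toehold GC < 40%, stem GC > 60%, stem |#G - #C| >= 4, bounded
homopolymers, and a dominant-stem secondary-structure check on both
hairpins.  The G/C-imbalance rule encodes the empirical finding that
stems with balanced G and C leak (polymerize without initiator), while
imbalances of 4-5 are quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import DesignConfig
from .seqcore import (
    gc_fraction,
    gc_imbalance,
    longest_homopolymer,
    max_complementary_run,
    normalize,
    reverse_complement,
)
from .thermo import (
    GeometryError,
    NNParameterSet,
    fold_check,
    fold_check_coords,
    load_default_parameters,
)

__all__ = [
    "HairpinSpec",
    "HairpinPair",
    "ReagentMetadata",
    "ConstraintReport",
    "RuleResult",
    "SearchFailure",
    "build_h1",
    "derive_partner",
    "derive_initiator",
    "apply_transition_shift",
    "validate_pair",
    "leakage_risk_class",
    "design_hairpin_pair",
    "orthogonality_check",
    "OrthogonalityReport",
    "fluorophore_compatibility",
    "FLUOROPHORES",
    "LINKERS",
]


class SearchFailure(RuntimeError):
    """Rejection-sampling budget exhausted before a fully passing design."""


@dataclass(frozen=True)
class HairpinSpec:
    """Domain decomposition of an H1 hairpin (all 5'->3' on the H1 strand)."""

    toehold: str
    stem: str
    loop: str
    shift: int = 0
    transition_bases: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "toehold", normalize(self.toehold))
        object.__setattr__(self, "stem", normalize(self.stem))
        object.__setattr__(self, "loop", normalize(self.loop))
        if self.shift not in (0, 1, 2):
            raise GeometryError("transition shift must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(self.toehold) + 2 * len(self.stem) + len(self.loop)


@dataclass(frozen=True)
class ReagentMetadata:
    """Fluorophore/linker choice and its empirical compatibility class."""

    fluorophore: str
    linker: str
    compatibility: str
    note: str = ""


@dataclass(frozen=True)
class HairpinPair:
    """A designed amplifier set: H1 spec+sequence, derived H2 and initiator."""

    spec: HairpinSpec
    h1: str
    h2: str
    initiator: str
    set_id: str = ""
    reagents: ReagentMetadata | None = None


@dataclass(frozen=True)
class RuleResult:
    name: str
    passed: bool
    value: float | str
    requirement: str
    mandatory: bool = True


@dataclass(frozen=True)
class ConstraintReport:
    """Per-rule outcome of validate_pair; passes iff every mandatory rule does."""

    rules: tuple[RuleResult, ...]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rules if r.mandatory)

    def __bool__(self) -> bool:
        return self.passed

    def failing(self) -> list[RuleResult]:
        return [r for r in self.rules if not r.passed]


def build_h1(spec: HairpinSpec) -> str:
    """H1 = toehold + stem + loop + stem', 5'->3'."""
    if len(spec.loop) < 3:
        raise GeometryError("loop must be at least 3 nt")
    return spec.toehold + spec.stem + spec.loop + reverse_complement(spec.stem)


def derive_partner(spec: HairpinSpec) -> str:
    """H2 = stem' + toehold' + stem + loop', 5'->3'.

    Consequences of the algebra: H2's stem pairs b with b'; its loop is
    a' (complementary to H1's toehold); its 3' toehold is c'
    (complementary to H1's loop); and the strand exposed when H2 opens
    is b' + a', the initiator.
    """
    if len(spec.loop) < 3:
        raise GeometryError("loop must be at least 3 nt")
    b_rc = reverse_complement(spec.stem)
    return b_rc + reverse_complement(spec.toehold) + spec.stem + reverse_complement(spec.loop)


def derive_initiator(spec: HairpinSpec) -> str:
    """Initiator = (toehold + stem)', 5'->3'; 21 nt for the default geometry."""
    return reverse_complement(spec.toehold + spec.stem)


def apply_transition_shift(spec: HairpinSpec, shift: int, paired: bool = True) -> HairpinSpec:
    """Move the stem/loop transition by 1-2 nt, lengthening the stem.

    One base from each loop end is repositioned per shift unit: the 5'
    loop base joins the stem (its partner on the 3' side becomes the
    complement), so a 9/12/9 spec becomes 9/13/7 at shift 1 and 9/14/5
    at shift 2 — total hairpin length is preserved.  This stabilizes a
    leaky hairpin without changing its length.

    With ``paired=False`` the transition bases stay single-stranded
    flanking the shortened loop (the sequence is unchanged; only the
    annotation records the shift), mirroring designs whose transition
    bases are left unpaired.
    """
    if shift == 0:
        return spec
    if shift not in (1, 2):
        raise GeometryError("shift must be 0, 1 or 2")
    if len(spec.loop) - 2 * shift < 3:
        raise GeometryError("loop too short for the requested transition shift")
    if not paired:
        return replace(
            spec,
            shift=spec.shift + shift,
            transition_bases=spec.transition_bases + spec.loop[:shift] + spec.loop[-shift:],
        )
    moved = spec.loop[:shift]
    return replace(
        spec,
        stem=spec.stem + moved,
        loop=spec.loop[shift:-shift],
        shift=spec.shift + shift,
        transition_bases=spec.transition_bases + moved,
    )


def leakage_risk_class(stem: str) -> str:
    """Initiator-independent HCR risk from the stem's G/C imbalance.

    Imbalance >= 4 -> "low" (the quiet regime observed empirically);
    2-3 -> "moderate" (mixed outcomes; an interpolation policy);
    0-1 -> "high" (balanced stems leak frequently).
    """
    imb = gc_imbalance(stem)
    if imb >= 4:
        return "low"
    if imb >= 2:
        return "moderate"
    return "high"


def validate_pair(
    pair: HairpinPair,
    params: NNParameterSet | None = None,
    config: DesignConfig | None = None,
) -> ConstraintReport:
    """Evaluate every published composition rule plus structural checks.

    Rules: (1) toehold GC < 40%; (2) stem GC > 60%; (3) stem G/C
    imbalance >= 4 (advisory if ``config.imbalance_mandatory`` is off);
    (4) dominant-stem fold check on H1 and H2; (5) cascade domain
    relations; (6) homopolymer cap.  Stem rules are evaluated on the
    written (5'-side) stem strand.
    """
    from .simulate import verify_cascade  # local import: simulate depends on nothing here

    params = params or load_default_parameters()
    config = config or DesignConfig()
    spec = pair.spec
    if pair.h1 != build_h1(spec):
        raise ValueError("pair.h1 is not the sequence its spec defines")

    rules: list[RuleResult] = []
    tgc = gc_fraction(spec.toehold)
    rules.append(
        RuleResult("toehold_gc", tgc < config.toehold_gc_max, round(tgc, 4),
                   f"< {config.toehold_gc_max:.2f}")
    )
    sgc = gc_fraction(spec.stem)
    rules.append(
        RuleResult("stem_gc", sgc > config.stem_gc_min, round(sgc, 4),
                   f"> {config.stem_gc_min:.2f}")
    )
    imb = gc_imbalance(spec.stem)
    rules.append(
        RuleResult("stem_imbalance", imb >= config.stem_imbalance_min, imb,
                   f">= {config.stem_imbalance_min}", mandatory=config.imbalance_mandatory)
    )
    f1 = fold_check(pair.h1, spec, params, config.fold_margin)
    la, lb, lc = len(spec.toehold), len(spec.stem), len(spec.loop)
    f2 = fold_check_coords(pair.h2, 0, lb + la, lb, params, config.fold_margin)
    rules.append(
        RuleResult("fold_h1", f1.passed,
                   round(f1.intended_dg37 - (f1.best_alternative_dg37 or 0.0), 3)
                   if f1.best_alternative_dg37 is not None else "no alternative",
                   f"margin >= {config.fold_margin} kcal/mol")
    )
    rules.append(
        RuleResult("fold_h2", f2.passed,
                   round(f2.intended_dg37 - (f2.best_alternative_dg37 or 0.0), 3)
                   if f2.best_alternative_dg37 is not None else "no alternative",
                   f"margin >= {config.fold_margin} kcal/mol")
    )
    cascade = verify_cascade(pair.h1, pair.h2, pair.initiator, spec)
    rules.append(RuleResult("cascade", cascade.passed,
                            "pass" if cascade.passed else cascade.first_failure or "fail",
                            "all five domain relations"))
    hp = max(longest_homopolymer(pair.h1), longest_homopolymer(pair.h2))
    rules.append(RuleResult("homopolymer", hp <= config.homopolymer_max, hp,
                            f"<= {config.homopolymer_max}"))
    return ConstraintReport(tuple(rules))


_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _draw(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def design_hairpin_pair(
    config: DesignConfig | None = None,
    seed: int = 0,
    params: NNParameterSet | None = None,
    set_id: str | None = None,
) -> HairpinPair:
    """Seeded rejection-sampling search for a fully compliant hairpin pair.

    Domains are drawn i.i.d. uniform over ACGT and filtered: the toehold
    and loop against the <40% GC band (the loop doubles as H2's toehold,
    so the toehold rule must hold for it too), the stem against the
    >60% GC and imbalance >= 4 rules.  Assembled candidates must then
    clear the homopolymer cap, both fold checks and the cascade check.
    Deterministic: the same seed and config always return the same pair.

    Raises
    ------
    SearchFailure
        If ``config.max_iterations`` domain draws are exhausted; the
        message names the constraint that rejected most candidates.
    """
    config = config or DesignConfig()
    params = params or load_default_parameters()
    rng = np.random.default_rng(seed)
    budget = config.max_iterations
    spent = 0
    reject_counts: dict[str, int] = {}

    def charge(rule: str) -> None:
        reject_counts[rule] = reject_counts.get(rule, 0) + 1

    def draw_filtered(n: int, ok) -> str:
        nonlocal spent
        while spent < budget:
            spent += 1
            s = _draw(rng, n)
            if ok(s):
                return s
        raise _budget_error()

    def _budget_error() -> SearchFailure:
        tight = max(reject_counts, key=reject_counts.get) if reject_counts else "budget"
        return SearchFailure(
            f"no compliant pair within {budget} draws (seed {seed}); "
            f"tightest constraint: {tight} ({reject_counts})"
        )

    def toehold_ok(s: str) -> bool:
        ok = (gc_fraction(s) < config.toehold_gc_max
              and longest_homopolymer(s) <= config.homopolymer_max)
        if not ok:
            charge("toehold_gc")
        return ok

    def stem_ok(s: str) -> bool:
        ok = (gc_fraction(s) > config.stem_gc_min
              and gc_imbalance(s) >= config.stem_imbalance_min
              and longest_homopolymer(s) <= config.homopolymer_max)
        if not ok:
            charge("stem_rules")
        return ok

    while spent < budget:
        a = draw_filtered(config.toehold_len, toehold_ok)
        b = draw_filtered(config.stem_len, stem_ok)
        c = draw_filtered(config.loop_len, toehold_ok)
        spec = HairpinSpec(a, b, c)
        if config.shift:
            spec = apply_transition_shift(
                spec, config.shift, paired=not config.keep_unpaired_transition
            )
        h1 = build_h1(spec)
        h2 = derive_partner(spec)
        pair = HairpinPair(
            spec, h1, h2, derive_initiator(spec),
            set_id=set_id if set_id is not None else f"S{seed}",
        )
        report = validate_pair(pair, params, config)
        if report.passed:
            return pair
        for r in report.failing():
            charge(r.name)
    raise _budget_error()


@dataclass(frozen=True)
class OrthogonalityReport:
    """Cross-talk screen over a panel of amplifier sets.

    ``runs[(i, j)]`` is the longest complementary run between set i's
    initiator (equal to every opened-hairpin tail in set i's polymer)
    and set j's toehold+stem recognition region; entries at or above the
    threshold are flagged.
    """

    n_sets: int
    threshold: int
    runs: dict[tuple[int, int], int]
    flagged: frozenset[tuple[int, int]]

    @property
    def passed(self) -> bool:
        return not self.flagged


def orthogonality_check(
    pairs: list[HairpinPair], config: DesignConfig | None = None
) -> OrthogonalityReport:
    """Screen a multiplex panel for initiator cross-talk.

    For every ordered combination of distinct sets, measures the longest
    complementary run between one set's initiator/exposed strand and the
    other set's toehold+stem region (the part an initiator must invade).
    """
    if len(pairs) < 2:
        raise ValueError("orthogonality check needs at least 2 hairpin pairs")
    config = config or DesignConfig()
    thr = config.crosstalk_run_threshold
    runs: dict[tuple[int, int], int] = {}
    flagged = set()
    for i, pi in enumerate(pairs):
        for j, pj in enumerate(pairs):
            if i == j:
                continue
            region = pj.spec.toehold + pj.spec.stem
            r = max_complementary_run(pi.initiator, region)
            runs[(i, j)] = r
            if r >= thr:
                flagged.add((i, j))
    return OrthogonalityReport(len(pairs), thr, runs, frozenset(flagged))


FLUOROPHORES = (
    "ATTO390", "FAM", "Alexa488", "ATTO488", "ATTO550", "ATTO565", "Alexa568", "Alexa647",
)
LINKERS = ("ssH", "C6")

# empirical gel-based compatibility of (fluorophore, linker) with efficient HCR
_COMPAT_NOTES = {
    ("ATTO550", "ssH"): ("recommended", "brightest signals; efficient HCR"),
    ("Alexa647", "ssH"): ("recommended", "brightest signals; efficient HCR"),
    ("ATTO550", "C6"): ("warn", "C6-linked ATTO550 hairpins failed to form ~10 kb products"),
}


def fluorophore_compatibility(fluor: str, linker: str = "ssH") -> ReagentMetadata:
    """Empirical compatibility of a fluorophore/linker choice with HCR.

    ATTO565 and Alexa568 reduce HCR efficiency with either linker;
    ATTO550 and Alexa647 on the ssH linker are the top performers; the
    C6 linker underperforms ssH, severely so for ATTO550.
    """
    if fluor not in FLUOROPHORES:
        raise ValueError(f"unknown fluorophore {fluor!r}; known: {FLUOROPHORES}")
    if linker not in LINKERS:
        raise ValueError(f"unknown linker {linker!r}; known: {LINKERS}")
    if fluor in ("ATTO565", "Alexa568"):
        return ReagentMetadata(fluor, linker, "warn",
                               "reduces HCR efficiency regardless of linker")
    if (fluor, linker) in _COMPAT_NOTES:
        cls, note = _COMPAT_NOTES[(fluor, linker)]
        return ReagentMetadata(fluor, linker, cls, note)
    if linker == "C6":
        return ReagentMetadata(fluor, linker, "acceptable",
                               "ssH linker gives higher HCR efficiency than C6")
    return ReagentMetadata(fluor, linker, "acceptable", "no interference observed")
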