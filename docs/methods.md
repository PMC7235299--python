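# Methods

## Domain model

A hairpin amplifier pair is fully determined by three domains on the H1
strand: toehold `a`, stem `b`, loop `c` (5'→3'). The partner hairpin and the
initiator are derived, never designed independently:

```
H1        = a + b + c + b'
H2        = b' + a' + b + c'
initiator = (a + b)' = b' + a'
```

Five string-level complementarity relations make the chain reaction run, and
`verify_cascade` checks them exactly: (1) the initiator is the reverse
complement of H1's toehold+stem; (2) H2's loop is `a'`; (3) H2's toehold is
`c'`; (4) H2's two stem copies pair; (5) the strand H2 exposes when opened
(`b' + a'`, its 5' stem copy plus loop) is again the initiator. Relation 5 is
what closes the catalytic cycle. H1's own stem self-pairing is a folding
property, not a cascade relation, and is covered by the fold check instead.

Default geometry is 9/12/9 (42 nt); toehold and loop lengths of 6–10 nt
(36–44 nt hairpins) are supported. Six-nt toeholds amplify poorly and are
permitted only for comparison studies.

### Transition shift

`apply_transition_shift` moves the stem/loop boundary by 1–2 nt: one base per
shift unit leaves each end of the loop, and the 5' base is paired into the
stem (9/12/9 → 9/13/7 → 9/14/5), preserving total length. This deepens the
stem and suppresses leakage at some cost in forward drive. A config flag
(`keep_unpaired_transition`) instead records the transition bases as
deliberately unpaired flanks of the shortened loop, leaving the sequence
untouched, for designs that keep single-base hinges at the transition.

## Composition rules and the leakage classifier

The designer enforces, as hard constraints (all evaluated on the written
strand; stem rules on the 5'-side stem copy, also after a transition shift —
the alternative of scoring only the original 12-nt core is noted but not
implemented):

| rule | default | rationale |
|---|---|---|
| toehold GC | < 0.40 (strict) | limits spurious invasion and leakage |
| stem GC | > 0.60 (strict) | monomer stability |
| stem \|#G − #C\| | ≥ 4 | balanced stems leak (see below) |
| homopolymer | ≤ 4 nt | synthesis quality, off-target simplicity |
| fold margin | 2.0 kcal/mol | intended stem must dominate alternatives |

The loop is sampled under the same < 0.40 GC band as the toehold because the
loop **is** the partner hairpin's toehold; any toehold rule that did not also
bind the loop would be violated by H2.

The imbalance rule comes from a 31-pair screening table (packaged as
`TABLE1`): stems with near-equal G and C counts show frequent
initiator-independent polymerization, stems with imbalance 4–5 rarely do.
`leakage_risk_class` encodes a three-level policy — imbalance ≥ 4 low,
2–3 moderate, 0–1 high; the moderate band is an interpolation (the screen
shows mixed outcomes there), documented as such. The rule is configurable to
advisory (`imbalance_mandatory=False`) since the evidence is correlational,
not mechanistic.

## Thermodynamics

`thermo` scores duplexes and hairpins with the unified DNA nearest-neighbor
parameter set (37 °C, 1 M Na⁺), shipped as versioned JSON package data
(10 unique stacks with ΔH/ΔS, duplex initiation, terminal A:T penalty;
ΔG°₃₇ = ΔH − 310.15 K · ΔS). Hairpin loop penalties are tabulated ΔG°₃₇
values for sizes 3–9, extended to size 30 (and beyond, at lookup time) by the
standard logarithmic extrapolation ΔG(n) = ΔG(n₀) + 1.75·R·T·ln(n/n₀); the
table is monotone non-decreasing beyond its minimum. Salt correction is out
of scope: every design decision compares candidates under one reference
condition, so only relative stabilities matter.

`fold_check` replaces a partition-function assessment with an explicit
contract: enumerate every internal complementary run ≥ 4 nt with a loop ≥ 3
(registers i+k : j+L−1−k), score each as stem stacks + loop penalty, discard
runs whose base pairs are a subset of the intended stem's pairs, and pass iff
the intended structure beats the best alternative by the configured margin
(default 2 kcal/mol — chosen so that random constraint-satisfying designs
pass while hairpins with a competing stem, e.g. a loop complementary to a
GC-rich toehold, fail). Runs that *extend* the intended stem (loop ends that
close one extra pair) count as alternatives, so the sampler implicitly avoids
loops with complementary termini. Dangling-end and coaxial terms are ignored;
pseudoknots and bimolecular misfolds are not modeled.

## Designer search

`design_hairpin_pair` is plain rejection sampling from
`numpy.random.default_rng(seed)`: draw toehold, stem and loop i.i.d. uniform
over ACGT, filter each domain against its cheap composition rules, then
assemble and test the expensive ones (homopolymers across junctions, both
fold checks, the cascade). The constraint space at these lengths is loose —
a few thousand base draws per accepted design, milliseconds per pair — so
no annealing is warranted. The iteration budget (default 10⁵ draws) turns a
pathological configuration into a `SearchFailure` naming the
tightest-rejecting constraint. One seed + one config → byte-identical output.

## Split-initiator probes

The 21-nt initiator splits 9 | 12 (positions 1–9: the 9-nt stem complement;
positions 10–21: the toehold complement plus first-3-nt stem complement).
The 39-nt probe carries the 12-nt half at its 5' end followed by a 2-nt
spacer and the reverse complement of the *upstream* 25-nt target window; the
36-nt probe carries the downstream binding site, spacer, and the 9-nt half at
its 3' end. Under antiparallel hybridization this juxtaposes the two halves
at the inter-window junction, reconstituting a contiguous initiator; the
alternative 5'→3' ordering of the toehold-complement block is geometrically
inconsistent with a junction-facing split and is not offered. The spacer
sequence is "AA" by default (unspecified in the source design; excluded from
GC and off-target accounting).

Window tiling scans every start position for adjacent (gap 0–2, default 0)
25-nt windows both inside the 45–55 % GC band with homopolymers ≤ 4.
`design_probe_set` then selects `n_pairs` non-overlapping pairs by a
maximal-spacing heuristic: bisection on the largest uniform start-to-start
spacing for which a leftmost-greedy sweep still finds `n_pairs`, which
spreads probes along the transcript deterministically (ties leftmost).
Off-target screening is exact complementary k-mer intersection (default
k = 15) against a background transcriptome, excluding the target's own id —
a deliberate stand-in for alignment-based homology search, exact for
perfect-match hits and blind to mismatched near-hits.

## Polymerization model

The simulator is structural, not kinetic: no rate constants are available
for these hairpins, so every feasible event is equiprobable. Events are
(i) an unbound initiator + free H1 → new polymer (dp = 1), (ii) a polymer
end whose next species (strict alternation, H1 first) is free → extension.
One event fires per step, chosen uniformly; the run stops at exhaustion or
`max_steps`. Consequences used as test oracles: hairpin conservation
(Σ dp = consumed), strict alternation in the event log, monotone mass
growth, and — with equal H1/H2 counts run to exhaustion — all hairpins
consumed, so mean dp = (n_H1 + n_H2)/n_init exactly. A polymer of dp
hairpins of length L nt is reported as a nicked duplex of dp·L/2 bp; gel
migration of nicked polymers is explicitly not modeled, so comparisons to
band positions are qualitative. Initiator-independent nucleation is off by
default (the designer's job is to make it negligible) and is not currently
parameterized.

Two closed forms accompany the simulator: `fold_amplification(target, L)` =
⌈2·target/L⌉ (477 for 10 kb at 42 nt — hence "at least ~400-fold"
amplification), and `synthesis_cost_ratio(new, old)` = 1 − new²/old² under a
quadratic per-mole cost model (0.6597 ≈ 66 % saving for 42 vs 72 nt).

## Rank statistics

`spearman_ties` assigns mid-ranks (scipy's average ranking), takes the
Pearson correlation ρ of the rank vectors, reports
S = (1 − ρ)·n(n² − 1)/6 (the classical sum-of-squared-rank-differences
statistic under the mid-rank convention), and a two-sided p-value from
t = ρ·√((n − 2)/(1 − ρ²)) with n − 2 df. The t approximation is used
unconditionally: the exact permutation null for S assumes no ties, and the
screening data are heavily tied. Constant vectors are an error, |ρ| = 1
maps to p = 0.

On `TABLE1`'s ordinal expansion (severity coded 1–4 in leakage order,
configurable) the association is ρ ≈ −0.44, p ≈ 0.013. The original screen
was analyzed on continuous band intensities that were never published; its
printed ρ = −0.40, S = 6941.8, p = 0.026 therefore cannot be reproduced from
the categorical counts, and the package's reproducible claim is the sign and
significance of the association, plus exact agreement with an independent
mid-rank Pearson oracle. This is stated here to prevent anyone "fixing" the
fixture toward the printed values.

## Synthetic transcripts

`synth_transcript` draws i.i.d. bases with P(G) = P(C) = gc/2, seeded. It
emulates only composition, not real mRNA features — no splice structure,
repeats, secondary-structure hotspots, or biased codon usage — so passing
probe-design tests on it demonstrates the designer's combinatorial
guarantees (window compliance, disjointness, initiator reconstitution,
screen correctness), not performance on any particular transcriptome. The
default study-scale inputs used throughout tests and the acceptance script
are 2-kb transcripts at 50 % GC, 100 designer seeds, and 500+500 hairpin /
5 initiator simulations — sizes at which every statistic used is already at
its asymptote (e.g. realized GC within ±0.03, full pool consumption).

## Known limitations

* Nearest-neighbor scoring omits salt/temperature dependence, dangling ends
  and coaxial stacking; the fold check enumerates duplex runs only.
* The off-target screen is exact-match k-mers; single-mismatch off-targets
  pass it.
* The polymerization model has no kinetics, reversibility, or spatial
  effects, and models leakage only by exclusion (designed away, not
  simulated).
* Fluorophore/linker guidance is a lookup of gel-derived outcomes for eight
  dyes and two linkers (ATTO550/Alexa647 on ssH recommended; ATTO565 and
  Alexa568 warn with any linker; ATTO550 on C6 warns), with no spectral or
  photochemical modeling.
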