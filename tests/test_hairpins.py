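import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shorthcr import (
    DesignConfig,
    HairpinPair,
    HairpinSpec,
    apply_transition_shift,
    build_h1,
    derive_initiator,
    derive_partner,
    design_hairpin_pair,
    fluorophore_compatibility,
    leakage_risk_class,
    orthogonality_check,
    validate_pair,
    verify_cascade,
)
from shorthcr.hairpins import SearchFailure
from shorthcr.seqcore import gc_fraction, gc_imbalance, reverse_complement
from shorthcr.thermo import GeometryError


def make_pair(spec, set_id="t"):
    return HairpinPair(spec, build_h1(spec), derive_partner(spec),
                       derive_initiator(spec), set_id=set_id)


class TestDomainAlgebra:
    def test_build_h1_small_example(self):
        assert build_h1(HairpinSpec("ATT", "GGCC", "TAA")) == "ATTGGCCTAAGGCC"

    def test_derive_partner_small_example(self):
        assert derive_partner(HairpinSpec("ATT", "GGCC", "TAA")) == "GGCCAATGGCCTTA"

    def test_derive_initiator_small_example(self):
        assert derive_initiator(HairpinSpec("ATT", "GGCC", "TAA")) == "GGCCAAT"

    @pytest.mark.parametrize("la,lc,expected_len", [(9, 9, 42), (6, 6, 36), (10, 10, 44)])
    def test_supported_geometries(self, la, lc, expected_len):
        spec = HairpinSpec("A" * (la - 2) + "GC", "GGTGGCGTGCAA", "T" * lc)
        assert len(build_h1(spec)) == expected_len
        assert len(derive_partner(spec)) == expected_len
        assert len(derive_initiator(spec)) == la + 12

    def test_tiny_loop_rejected(self):
        with pytest.raises(GeometryError):
            build_h1(HairpinSpec("ATT", "GGCC", "TA"))


class TestTransitionShift:
    def test_shift_one_gives_13_stem_7_loop(self):
        spec = HairpinSpec("ATTACATTA", "GGTGGCGTGCAA", "TCATTATCA")
        shifted = apply_transition_shift(spec, 1)
        assert (len(shifted.toehold), len(shifted.stem), len(shifted.loop)) == (9, 13, 7)
        assert len(build_h1(shifted)) == 42
        assert shifted.transition_bases == "T"

    def test_shift_two_gives_14_stem_5_loop(self):
        spec = HairpinSpec("ATTACATTA", "GGTGGCGTGCAA", "TCATTATCA")
        shifted = apply_transition_shift(spec, 2)
        assert (len(shifted.stem), len(shifted.loop)) == (14, 5)
        assert len(build_h1(shifted)) == 42  # 9 + 2*14 + 5

    def test_shift_zero_is_identity(self):
        spec = HairpinSpec("ATTACATTA", "GGTGGCGTGCAA", "TCATTATCA")
        assert apply_transition_shift(spec, 0) is spec

    def test_unpaired_mode_keeps_sequence(self):
        spec = HairpinSpec("ATTACATTA", "GGTGGCGTGCAA", "TCATTATCA")
        shifted = apply_transition_shift(spec, 1, paired=False)
        assert build_h1(shifted) == build_h1(spec)
        assert shifted.transition_bases == "TA"

    def test_short_loop_rejected(self):
        spec = HairpinSpec("ATTACATTA", "GGTGGCGTGCAA", "TCATTA")
        with pytest.raises(GeometryError):
            apply_transition_shift(spec, 2)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2]))
    def test_shift_preserves_total_length(self, seed, shift):
        import numpy as np

        rng = np.random.default_rng(seed)
        bases = "ACGT"
        a = "".join(bases[i] for i in rng.integers(0, 4, 9))
        b = "".join(bases[i] for i in rng.integers(0, 4, 12))
        c = "".join(bases[i] for i in rng.integers(0, 4, 9))
        spec = HairpinSpec(a, b, c)
        assert apply_transition_shift(spec, shift).length == spec.length


class TestValidation:
    def test_quoted_composition_examples(self):
        assert gc_fraction("ATTACAGTA") == pytest.approx(2 / 9)
        assert gc_fraction("GGACGTGCGTGA") == pytest.approx(8 / 12)
        assert gc_imbalance("GGACGTGCGTGA") == 4

    def test_balanced_stem_fails_imbalance_rule(self):
        spec = HairpinSpec("ATTACAGTA", "GGGCCCGGGCCC", "TCATTATCA")
        report = validate_pair(make_pair(spec))
        rule = {r.name: r for r in report.rules}["stem_imbalance"]
        assert not rule.passed
        assert not report.passed

    def test_advisory_imbalance_rule(self):
        cfg = DesignConfig(imbalance_mandatory=False)
        spec = HairpinSpec("ATTACAGTA", "GGAGCCGTGCAC", "TCATTATCA")  # imbalance 2
        report = validate_pair(make_pair(spec), config=cfg)
        assert {r.name: r for r in report.rules}["stem_imbalance"].mandatory is False

    def test_mismatched_h1_raises(self):
        spec = HairpinSpec("ATTACAGTA", "GGACGTGCGTGA", "TCATTATCA")
        bad = HairpinPair(spec, "A" * 42, derive_partner(spec), derive_initiator(spec))
        with pytest.raises(ValueError):
            validate_pair(bad)


class TestLeakageRisk:
    @pytest.mark.parametrize(
        "stem,expected",
        [
            ("GGGGGTGAGTTT", "low"),        # imbalance 5
            ("GGACGTGCGTGA", "low"),        # imbalance 4
            ("GGACGTGCGTCA", "moderate"),   # imbalance 2
            ("GGGCCCGGGCCC", "high"),       # imbalance 0
            ("GGGCCTGGGCCC", "high"),       # imbalance 1
        ],
    )
    def test_classes(self, stem, expected):
        assert leakage_risk_class(stem) == expected

    def test_monotone_in_imbalance(self):
        order = {"high": 0, "moderate": 1, "low": 2}
        stems = ["GCGCGCGCGCGC", "GCGCGCGCGCGG", "GCGCGCGCGGGG",
                 "GCGCGCGGGGGG", "GCGCGGGGGGGG", "GCGGGGGGGGGG"]
        ranks = [order[leakage_risk_class(s)] for s in stems]
        assert ranks == sorted(ranks)


class TestDesigner:
    def test_same_seed_identical_output(self):
        assert design_hairpin_pair(seed=11) == design_hairpin_pair(seed=11)

    def test_designed_pairs_satisfy_all_invariants(self, designed_pairs, default_config):
        for pair in designed_pairs[:25]:
            assert len(pair.h1) == len(pair.h2) == 42
            assert len(pair.initiator) == len(pair.spec.toehold) + len(pair.spec.stem)
            assert pair.initiator == reverse_complement(pair.spec.toehold + pair.spec.stem)
            assert validate_pair(pair, config=default_config).passed
            assert verify_cascade(pair.h1, pair.h2, pair.initiator, pair.spec).passed

    def test_designed_with_shift_keeps_length(self):
        cfg = DesignConfig(shift=1)
        pair = design_hairpin_pair(cfg, seed=3)
        assert len(pair.h1) == 42
        assert (len(pair.spec.stem), len(pair.spec.loop)) == (13, 7)
        assert validate_pair(pair, config=cfg).passed

    def test_budget_exhaustion_reports_tightest_constraint(self):
        cfg = DesignConfig(max_iterations=5)
        with pytest.raises(SearchFailure, match="tightest constraint"):
            design_hairpin_pair(cfg, seed=1)


class TestOrthogonality:
    def test_pair_against_itself_is_flagged(self, designed_pairs):
        p = designed_pairs[0]
        report = orthogonality_check([p, p])
        assert report.flagged  # full-length complementarity with itself
        assert report.runs[(0, 1)] == len(p.initiator)

    def test_runs_and_flags_match_brute_force(self, designed_pairs):
        """Cross-talk run lengths agree with an exhaustive substring oracle."""
        from Bio.Seq import Seq

        panel = designed_pairs[:3]
        report = orthogonality_check(panel)
        for (i, j), run in report.runs.items():
            region = panel[j].spec.toehold + panel[j].spec.stem
            query = str(Seq(panel[i].initiator).reverse_complement())
            brute = 0
            for a in range(len(query)):
                for b in range(a + 1, len(query) + 1):
                    if query[a:b] in region:
                        brute = max(brute, b - a)
            assert run == brute
            assert ((i, j) in report.flagged) == (run >= report.threshold)

    def test_needs_two_pairs(self, designed_pairs):
        with pytest.raises(ValueError):
            orthogonality_check(designed_pairs[:1])

    def test_matrix_complete_for_three_pairs(self, designed_pairs):
        report = orthogonality_check(designed_pairs[:3])
        assert set(report.runs) == {(i, j) for i in range(3) for j in range(3) if i != j}


class TestReagents:
    @pytest.mark.parametrize(
        "fluor,linker,expected",
        [
            ("ATTO550", "ssH", "recommended"),
            ("Alexa647", "ssH", "recommended"),
            ("Alexa568", "ssH", "warn"),
            ("ATTO565", "C6", "warn"),
            ("ATTO550", "C6", "warn"),
            ("FAM", "ssH", "acceptable"),
            ("ATTO488", "C6", "acceptable"),
        ],
    )
    def test_compatibility_table(self, fluor, linker, expected):
        meta = fluorophore_compatibility(fluor, linker)
        assert meta.compatibility == expected
        assert meta.note

    def test_unknown_fluorophore(self):
        with pytest.raises(ValueError, match="unknown fluorophore"):
            fluorophore_compatibility("Cy3", "ssH")
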