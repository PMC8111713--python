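import numpy as np
import pytest

from ampliphase.metrics import (
    attribute_haplotypes,
    count_errors,
    diff_events,
    identity,
    mean_rates,
    reduction,
    score_assembly,
)
from ampliphase.seqio import ReferenceSeq
from ampliphase.simulate import GroundTruth

from .conftest import random_seq
from .oracles import best_pairing_oracle


class TestDiffEvents:
    def test_identical_sequences_no_events(self):
        assert diff_events("ACGT", "ACGT") == []

    def test_substitutions_are_per_position_events(self):
        evs = diff_events("AAGTAC", "ACGTAT")
        assert [(e.pos, e.kind, e.allele) for e in evs] == [
            (1, "sub", "A"), (5, "sub", "C")
        ]

    def test_contiguous_deletion_is_one_event(self, rng):
        target = random_seq(rng, 400)
        query = target[:150] + target[200:]
        evs = diff_events(query, target)
        assert len(evs) == 1
        assert evs[0].kind == "del" and len(evs[0].allele) == 50

    def test_insertion_event(self, rng):
        target = random_seq(rng, 100)
        query = target[:40] + "TTTT" + target[40:]
        evs = diff_events(query, target)
        kinds = [(e.kind, e.allele) for e in evs]
        assert ("ins", "TTTT") in kinds and len(evs) == 1


class TestAttribution:
    def test_exact_match_identity_mapping(self, rng):
        haps = [ReferenceSeq(f"t{i}", random_seq(rng, 120)) for i in range(2)]
        asm = [ReferenceSeq(f"a{i}", haps[i].bases) for i in range(2)]
        assert attribute_haplotypes(asm, haps) == {"a0": "t0", "a1": "t1"}

    def test_swapped_labels_cross_over(self, rng):
        haps = [ReferenceSeq(f"t{i}", random_seq(rng, 120)) for i in range(2)]
        asm = [ReferenceSeq("a0", haps[1].bases), ReferenceSeq("a1", haps[0].bases)]
        assert attribute_haplotypes(asm, haps) == {"a0": "t1", "a1": "t0"}

    def test_three_haplotypes_match_exhaustive_oracle(self, rng):
        base = random_seq(rng, 150)
        haps = []
        for i in range(3):
            b = list(base)
            for p in rng.integers(0, 150, size=5 + 3 * i):
                b[p] = "ACGT"[rng.integers(4)]
            haps.append(ReferenceSeq(f"t{i}", "".join(b)))
        asm = []
        for i, h in enumerate(haps):
            b = list(h.bases)
            for p in rng.integers(0, 150, size=3):
                b[p] = "ACGT"[rng.integers(4)]
            asm.append(ReferenceSeq(f"a{i}", "".join(b)))
        sim = {
            (a.id, t.id): identity(a.bases, t.bases) for a in asm for t in haps
        }
        assert attribute_haplotypes(asm, haps) == best_pairing_oracle(sim)

    def test_count_mismatch_is_an_error(self, rng):
        haps = [ReferenceSeq("t", random_seq(rng, 50))]
        with pytest.raises(ValueError, match="counts"):
            attribute_haplotypes([], haps)


def _with_subs(seq, subs):
    b = list(seq)
    for p, allele in subs:
        b[p] = allele
    return "".join(b)


class TestCountErrors:
    @pytest.fixture
    def trio(self, rng):
        generic = random_seq(rng, 500)
        # target deviates from generic at 6 positions, alt at 6 others
        def alt_base(b, k=1):
            return "ACGT"[("ACGT".index(b) + k) % 4]

        t_pos = [50, 120, 200, 280, 360, 440]
        a_pos = [80, 150, 230, 310, 390, 470]
        target = _with_subs(generic, [(p, alt_base(generic[p])) for p in t_pos])
        alt = _with_subs(generic, [(p, alt_base(generic[p], 2)) for p in a_pos])
        return (
            ReferenceSeq("generic", generic),
            ReferenceSeq("target", target),
            ReferenceSeq("alt", alt),
        )

    def test_perfect_assembly(self, trio):
        generic, target, alt = trio
        assert count_errors(target, target, alt, generic) == (0, 0, 6)

    def test_single_variant_switch(self, trio):
        generic, target, alt = trio
        # assembled carries alt's allele at one of alt's variant positions
        asm = ReferenceSeq("asm", _with_subs(target.bases, [(80, alt.bases[80])]))
        assert count_errors(asm, target, alt, generic) == (0, 1, 6)

    def test_switch_run_collapses_and_novel_base_is_mismatch(self, trio):
        generic, target, alt = trio
        # three consecutive alt alleles plus one novel substitution
        subs = [(p, alt.bases[p]) for p in (150, 230, 310)]
        novel = 420
        novel_base = "ACGT"[("ACGT".index(target.bases[novel]) + 1) % 4]
        asm = ReferenceSeq("asm", _with_subs(target.bases, subs + [(novel, novel_base)]))
        mismatch, switch, dev = count_errors(asm, target, alt, generic)
        assert (mismatch, switch, dev) == (1, 1, 6)

    def test_intervening_mismatch_splits_switch_runs(self, trio):
        generic, target, alt = trio
        subs = [(150, alt.bases[150]), (310, alt.bases[310])]
        novel = 230
        novel_base = next(
            b for b in "ACGT"
            if b not in (target.bases[novel], alt.bases[novel])
        )
        asm = ReferenceSeq("asm", _with_subs(target.bases, subs + [(novel, novel_base)]))
        mismatch, switch, _ = count_errors(asm, target, alt, generic)
        assert (mismatch, switch) == (1, 2)

    def test_degenerate_attribution_rejected(self, trio, rng):
        generic, target, alt = trio
        junk = ReferenceSeq("junk", random_seq(rng, 500))
        with pytest.raises(ValueError, match="attribution"):
            count_errors(junk, target, alt, generic)


class TestRates:
    def test_rate_arithmetic(self, rng):
        generic = ReferenceSeq("g", random_seq(rng, 300))
        hap_a = ReferenceSeq("hap_A", _with_subs(generic.bases, [(50, "A" if generic.bases[50] != "A" else "C")]))
        b_subs = [(p, "G" if generic.bases[p] != "G" else "T") for p in (100, 150, 200, 250)]
        hap_b = ReferenceSeq("hap_B", _with_subs(generic.bases, b_subs))
        truth = GroundTruth(
            generic_reference=generic, haplotypes=[hap_a, hap_b], variant_table={}
        )
        report = score_assembly(
            [ReferenceSeq("x", hap_a.bases), ReferenceSeq("y", hap_b.bases)], truth
        )
        assert report.table["mismatch_rate"].tolist() == [0.0, 0.0]
        assert report.table["deviating_positions"].tolist() == [1, 4]

    def test_mean_rates_unweighted(self):
        class R:
            def __init__(self, m, s):
                self.mean_mismatch_rate, self.mean_switch_rate = m, s

        out = mean_rates([R(0.002, 0.0), R(0.006, 0.004)])
        assert out["mismatch_rate"] == pytest.approx(0.004)
        assert out["switch_rate"] == pytest.approx(0.002)


class TestReduction:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [
            (0.00398, 0.01033, 61.47),
            (0.00000, 0.00543, 100.00),
            (0.5, 0.5, 0.00),
        ],
    )
    def test_values(self, ref, other, expected):
        assert reduction(ref, other) == expected

    def test_zero_comparison_rate_undefined(self):
        with pytest.raises(ValueError):
            reduction(0.0, 0.0)
        with pytest.raises(ValueError):
            reduction(0.1, 0.0)

    def test_half_up_rounding(self):
        # 76.455 rounds up, not to even
        assert reduction(1 - 0.76455, 1.0) == 76.46
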