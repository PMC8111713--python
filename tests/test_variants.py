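import numpy as np
import pytest

from ampliphase.align import AlignedRead, Pileup, map_reads
from ampliphase.seqio import Read, ReferenceSeq
from ampliphase.simulate import simulate_long_reads
from ampliphase.variants import (
    HPSet,
    MISSING,
    ReadGenotypeMatrix,
    detect_hps,
    filter_genotype_matrix,
    filter_longreads_by_pwm,
    genotype_reads,
    pwm_from_pileup,
    score_read_against_pwm,
)

from .conftest import perfect_alignment, random_seq


def pileup_with(columns):
    pile = Pileup(len(columns))
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "del": 4}
    for p, col in enumerate(columns):
        for sym, n in col.items():
            pile.counts[p, code[sym]] = n
    return pile


class TestDetectHps:
    def test_balanced_het_position(self):
        hps = detect_hps(pileup_with([{"A": 50, "G": 50}]))
        assert hps.positions == [0]
        np.testing.assert_allclose(hps.allele_freqs[0], [0.5, 0, 0.5, 0])

    def test_minor_allele_below_threshold(self):
        hps = detect_hps(pileup_with([{"A": 85, "G": 15}]), maf=0.2)
        assert len(hps) == 0

    def test_gap_positions_never_hps(self):
        hps = detect_hps(pileup_with([{"A": 40, "del": 60}]), maf=0.2, min_depth=20)
        assert len(hps) == 0

    def test_min_depth_guard(self):
        hps = detect_hps(pileup_with([{"A": 5, "G": 5}]), min_depth=20)
        assert len(hps) == 0

    def test_third_allele_reported_not_carried(self):
        hps = detect_hps(pileup_with([{"A": 40, "G": 35, "T": 25}]), maf=0.2)
        assert hps.positions == [0]
        assert hps.extra_alleles == [(0, "T", 0.25)]

    def test_bed_export_is_half_open(self, tmp_path):
        hps = detect_hps(pileup_with([{"A": 50, "G": 50}]))
        p = tmp_path / "hps.bed"
        hps.to_bed(p, name="s")
        assert p.read_text() == "s\t0\t1\n"


def matrix(rows, positions=None):
    """rows: dict read id -> genotype string with '.' for missing."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3, ".": MISSING}
    ids = list(rows)
    codes = np.array([[code[ch] for ch in rows[i]] for i in ids], dtype=np.int8)
    return ReadGenotypeMatrix(
        read_ids=ids,
        positions=positions or list(range(codes.shape[1])),
        codes=codes,
    )


class TestGenotypeReads:
    def test_full_coverage_row(self, rng):
        ref = ReferenceSeq("r", random_seq(rng, 300))
        reads = simulate_long_reads(ref, depth=1, accuracy=1.0, seed=0)
        alns = map_reads(reads, ref)
        hps = HPSet(positions=list(range(10, 110, 10)), allele_freqs=np.zeros((10, 4)))
        m = genotype_reads(alns, hps, reference_bases=ref.bases)
        assert m.read_coverage()[0] == 1.0
        got = "".join("ACGT"[c] for c in m.codes[0])
        assert got == "".join(ref.bases[p] for p in hps.positions)

    def test_partial_span_coverage_fraction(self, rng):
        ref = ReferenceSeq("r", random_seq(rng, 300))
        aln = perfect_alignment("q", ref.bases[0:120], 0)
        hps = HPSet(positions=[20, 60, 100, 140, 180, 220, 260, 280, 290, 295],
                    allele_freqs=np.zeros((10, 4)))
        m = genotype_reads([aln], hps, reference_bases=ref.bases, realign=False)
        assert m.read_coverage()[0] == pytest.approx(0.3)

    def test_deletion_at_hp_is_missing(self):
        ref = ReferenceSeq("r", "ACGTACGTAC")
        aln = AlignedRead(
            read=Read("q", "ACGTCGTAC"), ref_offset=0,
            ops=[("match", 4, None), ("del", 1, None), ("match", 5, None)],
        )
        hps = HPSet(positions=[4], allele_freqs=np.zeros((1, 4)))
        m = genotype_reads([aln], hps, realign=False)
        assert m.codes[0, 0] == MISSING

    def test_empty_hpset_rejected(self):
        hps = HPSet(positions=[], allele_freqs=np.zeros((0, 4)))
        with pytest.raises(ValueError, match="homozygous"):
            genotype_reads([], hps)


class TestFilterGenotypeMatrix:
    def test_low_coverage_read_removed(self):
        m = matrix({
            "good": "ACGTACGTAC",
            "bad": "ACGTACGT..",  # 8/10 < 0.9
        })
        out = filter_genotype_matrix(m)
        assert out.read_ids == ["good"]

    def test_low_coverage_hp_removed_after_read_filter(self):
        rows = {f"r{i}": "AAAAAAAAA" + "." for i in range(9)}
        rows["r9"] = "A" * 10
        out = filter_genotype_matrix(matrix(rows), min_read_cov=0.9, min_hp_cov=0.3)
        # last HP covered by 1/10 surviving reads -> removed
        assert out.n_hps == 9

    def test_clean_matrix_unchanged(self):
        m = matrix({"a": "ACGT", "b": "TGCA"})
        out = filter_genotype_matrix(m)
        assert out.read_ids == ["a", "b"] and out.n_hps == 4

    def test_all_reads_removed_is_an_error(self):
        m = matrix({"a": "AC..", "b": "..GT"})
        with pytest.raises(ValueError, match="coverage"):
            filter_genotype_matrix(m)

    def test_filter_order_reaches_fixed_point(self):
        # removing reads can only lower HP coverage: re-applying the HP
        # filter after the read filter must change nothing
        rng = np.random.default_rng(5)
        rows = {}
        for i in range(30):
            geno = ["A" if rng.random() < 0.5 else "G" for _ in range(12)]
            for j in range(12):
                if rng.random() < 0.15:
                    geno[j] = "."
            rows[f"r{i}"] = "".join(geno)
        out = filter_genotype_matrix(matrix(rows), min_read_cov=0.8, min_hp_cov=0.3)
        again = filter_genotype_matrix(out, min_read_cov=0.8, min_hp_cov=0.3)
        assert again.read_ids == out.read_ids and again.positions == out.positions


class TestPwm:
    def test_frequencies_from_counts(self):
        pwm = pwm_from_pileup(pileup_with([{"A": 50, "G": 45, "T": 5}]))
        np.testing.assert_allclose(pwm.freqs[0], [0.5, 0, 0.45, 0.05, 0])

    def test_uniform_column(self):
        pwm = pwm_from_pileup(pileup_with([{"A": 5, "C": 5, "G": 5, "T": 5}]))
        np.testing.assert_allclose(pwm.freqs[0], [0.25] * 4 + [0])

    def test_zero_column_flagged_uninformative(self):
        pwm = pwm_from_pileup(pileup_with([{"A": 10}, {}]))
        assert pwm.informative.tolist() == [True, False]

    def test_random_read_scores_near_quarter_and_is_removed(self, rng):
        ref = ReferenceSeq("r", random_seq(rng, 200))
        sharp = pwm_from_pileup(
            Pileup(200)
        )
        # sharp PWM: every column 100% the reference base
        from ampliphase.align import build_pileup

        alns = [perfect_alignment(f"p{i}", ref.bases, 0) for i in range(5)]
        sharp = pwm_from_pileup(build_pileup(alns, 200))
        good = perfect_alignment("good", ref.bases, 0)
        noise = AlignedRead(
            read=Read("noise", random_seq(rng, 200)), ref_offset=0,
            ops=[("match", 200, None)],
        )
        assert score_read_against_pwm(good, sharp) == 1.0
        assert abs(score_read_against_pwm(noise, sharp) - 0.25) < 0.1
        kept = filter_longreads_by_pwm([good, noise], sharp, min_score=0.5)
        assert [a.read.id for a in kept] == ["good"]

    def test_disabled_stage_returns_input(self):
        alns = [perfect_alignment("a", "ACGT", 0)]
        assert filter_longreads_by_pwm(alns, None, None) == alns
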