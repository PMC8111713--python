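import numpy as np
import pytest

from ampliphase.simulate import (
    IndelSpec,
    ONT_RATIO,
    PACBIO_RATIO,
    SimConfig,
    apply_variant_table,
    inject_chimeras,
    simulate_dataset,
    simulate_haplotypes,
    simulate_long_reads,
    simulate_short_reads,
)


class TestHaplotypes:
    def test_snvs_only_differ_at_listed_positions(self):
        cfg = SimConfig(seed=5, n_snv=10, indels=[], homopolymers=[])
        truth = simulate_haplotypes(cfg)
        gen = truth.generic_reference.bases
        for h in truth.haplotypes:
            assert len(h.bases) == len(gen)
            diffs = [i for i, (a, b) in enumerate(zip(gen, h.bases)) if a != b]
            expected = sorted(v.ref_pos for v in truth.variant_table[h.id])
            assert diffs == expected
        # the two haplotypes differ at every SNV position
        a, b = truth.haplotypes
        assert sum(x != y for x, y in zip(a.bases, b.bases)) == 10

    def test_kb_scale_deletion_changes_length_exactly(self):
        cfg = SimConfig(
            seed=6, ref_length=8000, n_snv=4,
            indels=[IndelSpec(hap=1, length=2287, kind="del")],
            homopolymers=[],
        )
        truth = simulate_haplotypes(cfg)
        assert len(truth.haplotypes[0].bases) - len(truth.haplotypes[1].bases) == 2287

    def test_variant_table_reconstructs_haplotypes(self):
        for seed in (1, 2, 3):
            truth = simulate_haplotypes(SimConfig(seed=seed))
            for h in truth.haplotypes:
                rebuilt = apply_variant_table(
                    truth.generic_reference, truth.variant_table[h.id]
                )
                assert rebuilt == h.bases

    def test_seed_determinism(self):
        a = simulate_haplotypes(SimConfig(seed=7))
        b = simulate_haplotypes(SimConfig(seed=7))
        assert [h.bases for h in a.haplotypes] == [h.bases for h in b.haplotypes]

    def test_too_many_variants_rejected(self):
        with pytest.raises(ValueError, match="too many"):
            simulate_haplotypes(
                SimConfig(seed=0, ref_length=700, n_snv=2000,
                          indels=[], homopolymers=[])
            )


class TestShortReads:
    @pytest.fixture
    def hap(self):
        return simulate_haplotypes(SimConfig(seed=1)).haplotypes[0]

    def test_error_free_reads_are_exact_substrings(self, hap):
        rs = simulate_short_reads(hap, depth=5, err=0.0, seed=1)
        for r in rs.reads[:50]:
            assert r.bases in hap.bases

    def test_depth_arithmetic(self, hap):
        rs = simulate_short_reads(hap, depth=100, read_len=300, seed=2)
        total = sum(len(r.bases) for r in rs)
        realized = total / len(hap.bases)
        assert abs(realized - 100) <= 10  # within 10% of target

    def test_coverage_flat_at_termini(self, hap):
        rs = simulate_short_reads(hap, depth=200, read_len=300, err=0.0, seed=3)
        L = len(hap.bases)
        cov_start = sum(1 for r in rs if r.bases == hap.bases[: len(r.bases)])
        assert cov_start > 50  # the first base is well covered

    def test_determinism(self, hap):
        a = simulate_short_reads(hap, depth=10, seed=4)
        b = simulate_short_reads(hap, depth=10, seed=4)
        assert [r.bases for r in a] == [r.bases for r in b]


class TestLongReads:
    @pytest.fixture
    def hap(self):
        return simulate_haplotypes(SimConfig(seed=2)).haplotypes[0]

    def test_perfect_accuracy_reproduces_haplotype(self, hap):
        rs = simulate_long_reads(hap, depth=3, accuracy=1.0, seed=1)
        assert all(r.bases == hap.bases for r in rs)

    @pytest.mark.parametrize("ratio", [PACBIO_RATIO, ONT_RATIO])
    def test_injected_error_composition(self, hap, ratio):
        counter = {"sub": 0, "ins": 0, "del": 0}
        simulate_long_reads(hap, depth=30, accuracy=0.85, ratio=ratio,
                            seed=2, op_counter=counter)
        total = sum(counter.values())
        expected = np.array(ratio) / sum(ratio)
        got = np.array([counter["sub"], counter["ins"], counter["del"]]) / total
        np.testing.assert_allclose(got, expected, atol=0.02)

    def test_realized_identity_near_accuracy(self, hap):
        import edlib

        rs = simulate_long_reads(hap, depth=50, accuracy=0.85, seed=3)
        idents = [
            1 - edlib.align(r.bases, hap.bases, mode="NW")["editDistance"] / len(hap.bases)
            for r in rs
        ]
        assert abs(float(np.mean(idents)) - 0.85) < 0.02


class TestChimeras:
    def make_sets(self, n=100):
        truth = simulate_haplotypes(SimConfig(seed=3))
        return {
            h.id: simulate_long_reads(h, depth=n, accuracy=1.0, seed=i)
            for i, h in enumerate(truth.haplotypes)
        }

    def test_rate_zero_is_identity(self):
        sets = self.make_sets(10)
        combined, ids = inject_chimeras(sets, 0.0, seed=1)
        assert ids == [] and len(combined) == 20

    def test_rate_yields_expected_counts(self):
        sets = self.make_sets(100)
        combined, ids = inject_chimeras(sets, 0.1, seed=2)
        assert len(ids) == 20
        assert len(combined) == 200 - 20  # each chimera consumes two reads

    def test_chimera_has_one_breakpoint(self):
        sets = self.make_sets(50)
        truth = simulate_haplotypes(SimConfig(seed=3))
        a, b = truth.haplotypes
        combined, ids = inject_chimeras(sets, 0.1, seed=3)
        chim = next(r for r in combined if r.id == ids[0])
        # prefix from one haplotype, suffix from the other
        k = 100
        assert chim.bases[:k] in a.bases or chim.bases[:k] in b.bases
        assert chim.bases[-k:] in a.bases or chim.bases[-k:] in b.bases
        assert chim.bases not in a.bases and chim.bases not in b.bases


class TestDataset:
    def test_chimera_ids_recorded(self):
        ds = simulate_dataset(SimConfig(seed=4, chimera_rate=0.1))
        assert len(ds.truth.chimera_ids) == round(0.1 * 60)
        present = {r.id for r in ds.long_reads}
        assert set(ds.truth.chimera_ids) <= present

    def test_dataset_determinism(self):
        a = simulate_dataset(SimConfig(seed=5))
        b = simulate_dataset(SimConfig(seed=5))
        assert [r.bases for r in a.long_reads] == [r.bases for r in b.long_reads]
        assert [r.bases for r in a.short_reads.reads[:100]] == [
            r.bases for r in b.short_reads.reads[:100]
        ]
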