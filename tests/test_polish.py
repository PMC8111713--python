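import numpy as np
import pytest

from ampliphase.align import map_reads
from ampliphase.polish import (
    homopolymer_check,
    partition_short_reads,
    polish_haplotype,
    remap_and_verify,
)
from ampliphase.seqio import Read, ReadSet, ReferenceSeq
from ampliphase.simulate import simulate_short_reads
from ampliphase.variants import HPSet

from .conftest import random_seq


@pytest.fixture
def hap(rng):
    return ReferenceSeq("hap", random_seq(rng, 800))


def hpset(positions):
    return HPSet(positions=positions, allele_freqs=np.zeros((len(positions), 4)))


def cluster_genotypes(hps, alleles_by_cluster):
    """alleles_by_cluster: dict cluster -> string of bases, one per HP."""
    out = {}
    for c, bases in alleles_by_cluster.items():
        w = np.zeros((len(hps.positions), 4))
        for j, b in enumerate(bases):
            w[j, "ACGT".index(b)] = 1.0
        out[c] = w
    return out


class TestPartition:
    @pytest.fixture
    def setting(self, hap):
        # two HPs; cluster 0 carries the reference bases, cluster 1 alts
        positions = [200, 400]
        hps = hpset(positions)
        ref_alleles = "".join(hap.bases[p] for p in positions)
        alt = "".join("ACGT"[("ACGT".index(b) + 1) % 4] for b in ref_alleles)
        return hap, hps, cluster_genotypes(hps, {0: ref_alleles, 1: alt})

    def test_read_matching_one_cluster_goes_there_only(self, setting):
        hap, hps, genos = setting
        read = Read("r", hap.bases[150:450])  # covers both HPs, cluster 0
        part = partition_short_reads(map_reads([read], hap), hps, genos)
        assert [a.read.id for a in part.by_cluster[0]] == ["r"]
        assert part.by_cluster[1] == []
        assert part.unique_by_cluster[0] == {"r"}

    def test_hp_free_read_distributed_to_all(self, setting):
        hap, hps, genos = setting
        read = Read("r", hap.bases[500:700])
        part = partition_short_reads(map_reads([read], hap), hps, genos)
        assert all([a.read.id for a in part.by_cluster[c]] == ["r"] for c in (0, 1))
        assert part.hp_free_count == 1

    def test_tied_read_copied_to_all_and_counted_ambiguous(self, setting):
        hap, hps, genos = setting
        # one covered HP matches cluster 0, the other cluster 1
        bases = list(hap.bases[150:450])
        p = 400 - 150
        bases[p] = "ACGT"[("ACGT".index(hap.bases[400]) + 1) % 4]
        part = partition_short_reads(
            map_reads([Read("r", "".join(bases))], hap), hps, genos
        )
        assert part.ambiguous_reads == ["r"]
        assert all(len(part.by_cluster[c]) == 1 for c in (0, 1))

    def test_every_read_lands_in_at_least_one_partition(self, setting, rng):
        hap, hps, genos = setting
        reads = simulate_short_reads(hap, depth=30, read_len=150, seed=9)
        part = partition_short_reads(map_reads(reads, hap), hps, genos)
        seen = {a.read.id for c in part.by_cluster.values() for a in c}
        assert seen == {r.id for r in reads}


class TestPolishHaplotype:
    def test_error_free_reads_on_correct_draft(self, hap):
        reads = simulate_short_reads(hap, depth=60, read_len=200, err=0.0, seed=1)
        res = polish_haplotype(reads, hap)
        assert res.final_sequence == hap.bases
        assert not [p for p in res.problem_positions if p.blocking]

    def test_single_draft_error_corrected(self, hap):
        reads = simulate_short_reads(hap, depth=80, read_len=200, err=0.001, seed=2)
        wrong = list(hap.bases)
        wrong[333] = "ACGT"[("ACGT".index(wrong[333]) + 2) % 4]
        res = polish_haplotype(reads, ReferenceSeq("draft", "".join(wrong)))
        assert res.final_sequence == hap.bases

    def test_draft_deletion_restored_by_splice(self, hap):
        reads = simulate_short_reads(hap, depth=80, read_len=200, err=0.0, seed=3)
        draft = ReferenceSeq("draft", hap.bases[:350] + hap.bases[352:])
        res = polish_haplotype(reads, draft)
        assert res.final_sequence == hap.bases

    def test_mixed_partition_leaves_iupac_and_flags(self, hap, rng):
        # 50:50 contamination at one position -> residual heterozygosity
        other = list(hap.bases)
        other[400] = "ACGT"[("ACGT".index(other[400]) + 1) % 4]
        mix = ReadSet(
            simulate_short_reads(hap, depth=40, read_len=200, err=0.0, seed=4).reads
            + simulate_short_reads(
                ReferenceSeq("o", "".join(other)), depth=40, read_len=200,
                err=0.0, seed=5
            ).reads,
            "short",
        )
        res = polish_haplotype(mix, hap)
        flagged = [p for p in res.problem_positions
                   if p.kind == "residual_heterozygosity"]
        assert [p.position for p in flagged] == [400]
        assert res.final_sequence[400] not in "ACGT"  # IUPAC code

    def test_no_short_reads_returns_unpolished_draft(self, hap):
        res = polish_haplotype(ReadSet([], "short"), hap)
        assert res.unpolished and res.final_sequence == hap.bases


class TestHomopolymerCheck:
    def make_run_ref(self, rng, run_len, base="A"):
        left = random_seq(rng, 300).rstrip(base)
        right = random_seq(rng, 300).lstrip(base)
        return ReferenceSeq("h", left + base * run_len + right), len(left)

    def test_consistent_run(self, rng):
        ref, start = self.make_run_ref(rng, 14)
        reads = simulate_short_reads(ref, depth=40, read_len=150, err=0.0, seed=6)
        report = homopolymer_check(map_reads(reads, ref), ref, min_hp_len=8)
        (run,) = report.runs
        assert (run.position, run.consensus_length) == (start, 14)
        assert run.mode_length == 14 and run.consistent

    def test_consensus_error_flagged(self, rng):
        ref, start = self.make_run_ref(rng, 17)
        reads = simulate_short_reads(ref, depth=40, read_len=150, err=0.0, seed=7)
        # consensus claims 16 although reads support 17
        wrong = ReferenceSeq("h", ref.bases[:start] + ref.bases[start + 1 :])
        report = homopolymer_check(map_reads(reads, wrong), wrong, min_hp_len=8)
        (run,) = report.runs
        assert run.consensus_length == 16 and run.mode_length == 17
        assert not run.consistent
        assert report.problems()[0].kind == "homopolymer_mismatch"

    def test_short_runs_not_checked(self, rng):
        ref, _ = self.make_run_ref(rng, 7)
        reads = simulate_short_reads(ref, depth=20, read_len=150, err=0.0, seed=8)
        report = homopolymer_check(map_reads(reads, ref), ref, min_hp_len=8)
        assert report.runs == []

    def test_no_spanning_reads_uncheckable(self, rng):
        ref, start = self.make_run_ref(rng, 10)
        report = homopolymer_check([], ref, min_hp_len=8)
        (run,) = report.runs
        assert not run.checkable and run.consistent is None


class TestRemapAndVerify:
    @pytest.fixture
    def polished(self, hap):
        reads = simulate_short_reads(hap, depth=60, read_len=200, err=0.0, seed=10)
        return hap, reads

    def test_unedited_reference_is_resolved(self, polished):
        hap, reads = polished
        reports = remap_and_verify([hap], {"hap": reads})
        assert reports["hap"].resolved
        assert reports["hap"].consensus_mismatches == []

    def test_wrong_edit_surfaces_as_consensus_mismatch(self, polished):
        hap, reads = polished
        bad = list(hap.bases)
        bad[250] = "ACGT"[("ACGT".index(bad[250]) + 1) % 4]
        reports = remap_and_verify(
            [ReferenceSeq("hap", "".join(bad))], {"hap": reads}
        )
        assert not reports["hap"].resolved
        positions = [p for p, _, _ in reports["hap"].consensus_mismatches]
        assert positions == [250]

    def test_correct_edit_resolves_problem(self, polished, rng):
        hap, reads = polished
        # start from a reference carrying a wrong base; the edit fixes it
        bad = list(hap.bases)
        bad[250] = "ACGT"[("ACGT".index(bad[250]) + 1) % 4]
        before = remap_and_verify([ReferenceSeq("hap", "".join(bad))], {"hap": reads})
        after = remap_and_verify([hap], {"hap": reads})
        assert not before["hap"].resolved and after["hap"].resolved

    def test_id_mismatch_is_an_error(self, polished):
        hap, reads = polished
        with pytest.raises(ValueError, match="hap"):
            remap_and_verify([ReferenceSeq("wrong", hap.bases)], {"hap": reads})
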