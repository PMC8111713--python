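import warnings

import numpy as np
import pytest

from ampliphase.cluster import (
    build_psdm,
    cluster_pwms,
    cluster_reads,
    membership_coefficients,
    prune_reads,
)
from ampliphase.variants import MISSING, ReadGenotypeMatrix


def matrix_from(rows):
    code = {"A": 0, "C": 1, "G": 2, "T": 3, ".": MISSING}
    ids = list(rows)
    codes = np.array([[code[ch] for ch in rows[i]] for i in ids], dtype=np.int8)
    return ReadGenotypeMatrix(
        read_ids=ids, positions=list(range(codes.shape[1])), codes=codes
    )


def two_group_matrix(n_per=20, n_hps=10, err=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(n_per):
        g = ["A"] * n_hps
        rows[f"a{i}"] = g
    for i in range(n_per):
        rows[f"b{i}"] = ["G"] * n_hps
    if err:
        for rid, g in rows.items():
            for j in range(n_hps):
                if rng.random() < err:
                    g[j] = "ACGT"[rng.integers(4)]
    return matrix_from({k: "".join(v) for k, v in rows.items()})


class TestPsdm:
    def test_weighting_follows_allele_frequencies(self):
        # a position with 50% A / 45% G / 5% T: an A-vs-G disagreement is the
        # major-major conflict (weight 1 after rescaling); A-vs-T only
        # 0.025 / 0.225
        weights = np.array([[0.50, 0.0, 0.45, 0.05]])
        m = matrix_from({"r1": "A", "r2": "G", "r3": "T"})
        d = build_psdm(m, weights=weights, min_shared_hps=1)
        ag = d.values[0, 1]
        at = d.values[0, 2]
        assert ag == pytest.approx(1.0)
        assert at == pytest.approx(0.025 / 0.225)
        assert at < ag

    def test_identical_rows_zero_distance(self):
        m = matrix_from({"r1": "ACGT", "r2": "ACGT"})
        d = build_psdm(m, min_shared_hps=1)
        assert d.values[0, 1] == 0.0

    def test_opposite_haplotypes_distance_one(self):
        m = two_group_matrix(n_per=5)
        d = build_psdm(m)
        assert d.values[0, 5] == pytest.approx(1.0)
        assert np.allclose(np.diag(d.values), 0.0)
        assert np.allclose(d.values, d.values.T)

    def test_insufficient_shared_hps_missing(self):
        m = matrix_from({"r1": "AC..", "r2": "..GT", "r3": "ACGT"})
        d = build_psdm(m, min_shared_hps=2)
        assert np.isnan(d.values[0, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = d.imputed()
        assert not np.isnan(filled).any()


class TestClusterReads:
    def test_two_well_separated_groups_recovered_exactly(self):
        m = two_group_matrix(n_per=20, err=0.03, seed=1)
        cl = cluster_reads(build_psdm(m), expected_n=2)
        assert len(cl.retained_clusters) == 2
        parts = sorted(
            (frozenset(cl.members(c)) for c in cl.retained_clusters), key=sorted
        )
        assert parts[0] == {f"a{i}" for i in range(20)}
        assert parts[1] == {f"b{i}" for i in range(20)}

    def test_chimera_cluster_midway_not_retained(self):
        rows = {f"a{i}": "A" * 12 for i in range(12)}
        rows.update({f"b{i}": "G" * 12 for i in range(12)})
        # small chimeric cluster halfway between the haplotypes
        rows.update({f"c{i}": "A" * 6 + "G" * 6 for i in range(6)})
        cl = cluster_reads(build_psdm(matrix_from(rows)), expected_n=2,
                           min_cluster_size=5)
        retained_members = {
            rid for c in cl.retained_clusters for rid in cl.members(c)
        }
        assert not any(r.startswith("c") for r in retained_members)

    def test_homozygous_single_cluster_with_warning(self):
        m = matrix_from({f"r{i}": "AAAA" for i in range(12)})
        with pytest.warns(UserWarning, match="homozygosity"):
            cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=3)
        assert len(cl.retained_clusters) == 1

    def test_too_few_reads_rejected(self):
        m = two_group_matrix(n_per=2)
        with pytest.raises(ValueError, match="reads"):
            cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=5)


class TestMembership:
    @pytest.fixture
    def clustered(self):
        m = two_group_matrix(n_per=10)
        cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=3)
        return m, cl

    def test_pure_reads_at_extremes(self, clustered):
        m, cl = clustered
        sc = membership_coefficients(m, cl)
        mag = np.abs(sc.coefficient)
        np.testing.assert_allclose(mag, 1.0)
        signs = {rid: c for rid, c in zip(sc.read_ids, np.sign(sc.coefficient))}
        assert len({signs[f"a{i}"] for i in range(10)}) == 1
        assert signs["a0"] != signs["b0"]

    def test_chimera_scores_near_zero(self):
        rows = {f"a{i}": "A" * 10 for i in range(10)}
        rows.update({f"b{i}": "G" * 10 for i in range(10)})
        rows["chimera"] = "A" * 5 + "G" * 5
        m = matrix_from(rows)
        cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=3)
        sc = membership_coefficients(m, cl)
        coef = dict(zip(sc.read_ids, sc.coefficient))
        assert abs(coef["chimera"]) < 0.05
        assert abs(coef["a0"]) > 0.9

    def test_cluster_pwms_members_override(self, clustered):
        m, cl = clustered
        full = cluster_pwms(m, cl)
        sub = cluster_pwms(m, cl, members={c: cl.members(c)[:5] for c in cl.retained_clusters})
        for c in cl.retained_clusters:
            np.testing.assert_allclose(full[c], sub[c])  # pure clusters: same PWM


class TestPrune:
    def test_floor_drops_chimeras_keeps_clean_reads(self):
        rows = {f"a{i}": "A" * 10 for i in range(100)}
        rows.update({f"b{i}": "G" * 10 for i in range(100)})
        rows.update({f"chim{i}": "A" * 5 + "G" * 5 for i in range(10)})
        m = matrix_from(rows)
        cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=5)
        sc = membership_coefficients(m, cl)
        kept = prune_reads(sc, retain_quantile=0.25, coef_floor=0.2)
        all_kept = {r for ids in kept.values() for r in ids}
        assert not any(r.startswith("chim") for r in all_kept)
        clean_kept = sum(1 for r in all_kept if not r.startswith("chim"))
        assert clean_kept >= 0.95 * 200

    def test_identity_when_quantile_one_and_no_floor(self):
        m = two_group_matrix(n_per=10)
        cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=3)
        sc = membership_coefficients(m, cl)
        kept = prune_reads(sc, retain_quantile=1.0, coef_floor=0.0,
                           min_cluster_size=3)
        assert sum(len(v) for v in kept.values()) == 20

    def test_cluster_collapsing_below_min_size_is_an_error(self):
        # graded coefficients: an aggressive quantile leaves too few reads
        rows = {f"a{i}": "A" * (10 - i) + "G" * i for i in range(6)}
        rows.update({f"b{i}": "G" * 10 for i in range(6)})
        m = matrix_from(rows)
        cl = cluster_reads(build_psdm(m), expected_n=2, min_cluster_size=3)
        sc = membership_coefficients(m, cl)
        with pytest.raises(ValueError, match="min_cluster_size"):
            prune_reads(sc, retain_quantile=0.95, coef_floor=0.2,
                        min_cluster_size=5)
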