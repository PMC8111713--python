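"""Long-read haplotype clustering.

Reads are clustered on a Position-Specific Distance Matrix (PSDM) built from
their genotypes at heterozygous positions, with each position's contribution
weighted by its allele frequencies so that disagreements between major
genotypes count more than disagreements involving rare (likely erroneous)
bases. Hierarchical clustering with an adaptive cut yields the haplotype
clusters; all reads are then re-scored against per-cluster PWMs to obtain
haplotype membership coefficients, and only the best-representing fraction
of reads per cluster is retained — which eliminates PCR chimeras as long as
they stay less abundant than reads true to the actual alleles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .variants import MISSING, ReadGenotypeMatrix

#: Pairs sharing fewer HPs than this have no meaningful distance.
DEFAULT_MIN_SHARED_HPS = 3

#: Keep the best 75% of reads per cluster, and never keep a read whose
#: |coefficient| is below the absolute floor — near-zero coefficients mark
#: chimeras and noise reads.
DEFAULT_RETAIN_QUANTILE = 0.25
DEFAULT_COEF_FLOOR = 0.2

#: A cut producing a relative merge-height gap below this is considered no
#: structure at all (single cluster).
MIN_RELATIVE_GAP = 0.2


def default_min_cluster_size(n_reads: int) -> int:
    return max(5, int(round(0.05 * n_reads)))


def hp_weights(m: ReadGenotypeMatrix) -> np.ndarray:
    """Per-HP base frequencies over non-missing entries, shape (n_hps, 4)."""
    w = np.zeros((m.n_hps, 4))
    for j in range(m.n_hps):
        col = m.codes[:, j]
        col = col[col != MISSING]
        if len(col):
            w[j] = np.bincount(col, minlength=4) / len(col)
    return w


@dataclass
class PSDM:
    """Square symmetric read-by-read weighted distance matrix."""

    read_ids: list[str]
    values: np.ndarray  # (n, n), NaN where pairs share too few HPs
    shared: np.ndarray  # (n, n) co-covered HP counts

    def __len__(self) -> int:
        return len(self.read_ids)

    def imputed(self) -> np.ndarray:
        vals = self.values.copy()
        miss = np.isnan(vals)
        if miss.any():
            warnings.warn(
                f"{int(miss.sum()) // 2} read pairs share too few HPs; "
                "imputing the matrix maximum for clustering",
                stacklevel=2,
            )
            vals[miss] = np.nanmax(vals) if np.isfinite(np.nanmax(vals)) else 1.0
        return vals


def build_psdm(
    m: ReadGenotypeMatrix,
    weights: Optional[np.ndarray] = None,
    min_shared_hps: int = DEFAULT_MIN_SHARED_HPS,
) -> PSDM:
    """Position-specific distance matrix over reads.

    distance(r, s) = mean over co-covered HPs p of d_p(a, b), where
    d_p(a, a) = 0 and, for a != b, d_p(a, b) = w_p(a) * w_p(b) rescaled so
    that the largest product over distinct base pairs at p equals 1 (the
    major-major disagreement scores 1 at every position).
    """
    if weights is None:
        weights = hp_weights(m)
    n, k = m.n_reads, m.n_hps
    # per-HP 5x5 distance tables (MISSING handled via masking)
    tables = np.zeros((k, 4, 4))
    for p in range(k):
        w = weights[p]
        prod = np.outer(w, w)
        np.fill_diagonal(prod, 0.0)
        mx = prod.max()
        if mx > 0:
            tables[p] = prod / mx
        np.fill_diagonal(tables[p], 0.0)
    codes = m.codes
    covered = codes != MISSING
    dist_sum = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for p in range(k):
        cov = covered[:, p]
        idx = np.nonzero(cov)[0]
        c = codes[idx, p].astype(int)
        d = tables[p][np.ix_(c, c)]
        dist_sum[np.ix_(idx, idx)] += d
        shared[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(shared >= min_shared_hps, dist_sum / np.maximum(shared, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return PSDM(read_ids=list(m.read_ids), values=values, shared=shared)


@dataclass
class HaplotypeClustering:
    """Result of hierarchical clustering with adaptive cut.

    ``labels`` maps read id to its cluster id; ``retained_clusters`` are the
    cluster ids kept (most distant first when a selection was needed).
    """

    labels: dict[str, int]
    merge_heights: np.ndarray
    retained_clusters: list[int]
    expected_n: int
    warnings: list[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return [r for r, c in self.labels.items() if c == cluster_id]


def _adaptive_n_clusters(heights: np.ndarray, max_k: int) -> int:
    """Number of clusters maximizing the relative gap between successive
    merge heights; 1 when no gap is convincing."""
    n_merges = len(heights)
    top = heights[-1] if n_merges else 0.0
    if top <= 0:
        return 1
    best_k, best_gap = 1, MIN_RELATIVE_GAP
    for k in range(2, min(max_k, n_merges) + 1):
        gap = (heights[n_merges - k + 1] - heights[n_merges - k]) / top
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def _mean_inter_distance(vals: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float(vals[np.ix_(a, b)].mean())


def cluster_reads(
    d: PSDM,
    expected_n: int = 2,
    min_cluster_size: Optional[int] = None,
) -> HaplotypeClustering:
    """Average-linkage hierarchical clustering of the PSDM with an adaptive
    cut (largest relative merge-height gap, runts merged into their nearest
    cluster). If more clusters than expected are found, the ``expected_n``
    mutually most distant clusters are retained (greedy max-min selection;
    ties broken by larger size, then lower cluster id)."""
    n = len(d)
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(n)
    if n < 2 * min_cluster_size:
        raise ValueError(
            f"need at least {2 * min_cluster_size} reads to attempt clustering, got {n}"
        )
    vals = d.imputed()
    sym = np.clip((vals + vals.T) / 2, 0.0, None)
    np.fill_diagonal(sym, 0.0)
    Z = _scipy_linkage(squareform(sym, checks=False), method="average")
    heights = Z[:, 2]
    notes: list[str] = []
    k = _adaptive_n_clusters(heights, max_k=max(expected_n * 3, 4))
    labels = fcluster(Z, t=k, criterion="maxclust") if k > 1 else np.ones(n, dtype=int)

    # merge clusters below the minimum size into their nearest neighbour
    def sizes() -> dict[int, int]:
        u, c = np.unique(labels, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))

    changed = True
    while changed:
        changed = False
        sz = sizes()
        if len(sz) <= 1:
            break
        small = [c for c, s in sorted(sz.items(), key=lambda x: x[1]) if s < min_cluster_size]
        if not small:
            break
        c0 = small[0]
        members = np.nonzero(labels == c0)[0]
        others = [c for c in sz if c != c0]
        nearest = min(
            others,
            key=lambda c: _mean_inter_distance(sym, members, np.nonzero(labels == c)[0]),
        )
        labels[members] = nearest
        changed = True

    unique = sorted(np.unique(labels).tolist())
    if len(unique) < expected_n:
        notes.append(
            f"found {len(unique)} cluster(s), expected {expected_n}: "
            "homozygosity candidate"
        )
        warnings.warn(notes[-1], stacklevel=2)
        retained = unique
    elif len(unique) > expected_n:
        # greedy max-min selection of the most distant clusters
        idx_of = {c: np.nonzero(labels == c)[0] for c in unique}
        sz = sizes()

        def tie_key(c: int) -> tuple:
            return (sz[c], -c)

        pair = max(
            itertools.combinations(unique, 2),
            key=lambda p: (
                _mean_inter_distance(sym, idx_of[p[0]], idx_of[p[1]]),
                tie_key(p[0]),
                tie_key(p[1]),
            ),
        )
        retained = list(pair)
        while len(retained) < expected_n:
            cand = [c for c in unique if c not in retained]
            retained.append(
                max(
                    cand,
                    key=lambda c: (
                        min(
                            _mean_inter_distance(sym, idx_of[c], idx_of[r])
                            for r in retained
                        ),
                        tie_key(c),
                    ),
                )
            )
        notes.append(
            f"{len(unique)} clusters found; retained the {expected_n} most distant"
        )
    else:
        retained = unique
    return HaplotypeClustering(
        labels={rid: int(c) for rid, c in zip(d.read_ids, labels)},
        merge_heights=heights,
        retained_clusters=[int(c) for c in retained],
        expected_n=expected_n,
        warnings=notes,
    )


@dataclass
class MembershipScores:
    """Per-read scores against each retained cluster's PWM.

    For two clusters the signed coefficient (S_A - S_B) / (S_A + S_B) lives
    in [-1, 1]; its sign identifies the assigned cluster. For more clusters
    the margin between best and second-best score plays the same role.
    """

    read_ids: list[str]
    cluster_ids: list[int]
    scores: np.ndarray  # (n_reads, n_clusters)
    assigned: np.ndarray  # (n_reads,) index into cluster_ids
    coefficient: np.ndarray  # (n_reads,) signed (2 clusters) or margin

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, index=self.read_ids,
            columns=[f"S_{c}" for c in self.cluster_ids],
        )
        df["assigned"] = [self.cluster_ids[a] for a in self.assigned]
        df["coefficient"] = self.coefficient
        return df


def cluster_pwms(
    m: ReadGenotypeMatrix,
    clustering: HaplotypeClustering,
    members: Optional[dict[int, list[str]]] = None,
) -> dict[int, np.ndarray]:
    """Per retained cluster, the PWM over its members' genotype columns.

    ``members`` overrides the cluster membership (e.g. with the pruned read
    sets, so chimeras and noise reads no longer contribute)."""
    pwms = {}
    for c in clustering.retained_clusters:
        ids = set(members[c]) if members is not None else set(clustering.members(c))
        mask = np.array([r in ids for r in m.read_ids])
        sub = ReadGenotypeMatrix(
            read_ids=[r for r in m.read_ids if r in ids],
            positions=m.positions,
            codes=m.codes[mask],
        )
        pwms[c] = hp_weights(sub)
    return pwms


def membership_coefficients(
    m: ReadGenotypeMatrix, clustering: HaplotypeClustering
) -> MembershipScores:
    """Re-score every read against the retained clusters' PWMs.

    A read's score for a cluster is the mean, over its non-missing HPs with
    an informative cluster PWM column, of the PWM frequency of the read's
    base. With two clusters the haplotype membership coefficient is
    (S_A - S_B) / (S_A + S_B), 0 when both scores are 0.
    """
    if not clustering.retained_clusters:
        raise ValueError("no retained clusters to score against")
    pwms = cluster_pwms(m, clustering)
    cids = clustering.retained_clusters
    n = m.n_reads
    scores = np.zeros((n, len(cids)))
    for ci, c in enumerate(cids):
        w = pwms[c]
        informative = w.sum(axis=1) > 0
        for i in range(n):
            codes = m.codes[i]
            ok = (codes != MISSING) & informative
            if ok.any():
                scores[i, ci] = w[np.nonzero(ok)[0], codes[ok].astype(int)].mean()
    assigned = scores.argmax(axis=1)
    if len(cids) == 2:
        tot = scores.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            coefficient = np.where(tot > 0, (scores[:, 0] - scores[:, 1]) / tot, 0.0)
    elif len(cids) == 1:
        coefficient = scores[:, 0]
    else:
        part = np.sort(scores, axis=1)
        tot = scores.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            coefficient = np.where(tot > 0, (part[:, -1] - part[:, -2]) / tot, 0.0)
    return MembershipScores(
        read_ids=list(m.read_ids),
        cluster_ids=list(cids),
        scores=scores,
        assigned=assigned,
        coefficient=coefficient,
    )


def prune_reads(
    scores: MembershipScores,
    retain_quantile: float = DEFAULT_RETAIN_QUANTILE,
    coef_floor: float = DEFAULT_COEF_FLOOR,
    min_cluster_size: int = 5,
) -> dict[int, list[str]]:
    """Keep, per cluster, the reads best representing it.

    Within each cluster's assigned reads, reads with |coefficient| above the
    cluster's ``retain_quantile`` quantile are retained; reads below the
    absolute ``coef_floor`` are always dropped (chimeras and noise sit near
    zero). Raises when a cluster retains fewer than ``min_cluster_size``
    reads.
    """
    if not 0 < retain_quantile <= 1:
        raise ValueError("retain_quantile must be in (0, 1]")
    out: dict[int, list[str]] = {}
    mag = np.abs(scores.coefficient)
    for ci, c in enumerate(scores.cluster_ids):
        mask = scores.assigned == ci
        ids = [r for r, m_ in zip(scores.read_ids, mask) if m_]
        vals = mag[mask]
        if len(vals) == 0:
            raise ValueError(f"cluster {c} has no assigned reads")
        if retain_quantile == 1.0:
            cut = -np.inf
        else:
            cut = np.quantile(vals, retain_quantile)
        keep = [
            r for r, v in zip(ids, vals) if v >= max(cut, coef_floor)
        ]
        if retain_quantile == 1.0 and coef_floor <= 0:
            keep = ids
        if len(keep) < min_cluster_size:
            raise ValueError(
                f"cluster {c} retains only {len(keep)} reads "
                f"(< min_cluster_size {min_cluster_size}) after pruning"
            )
        out[c] = keep
    total = sum(len(v) for v in out.values())
    if total < 0.4 * len(scores.read_ids):
        warnings.warn(
            "more than 60% of reads pruned: chimera/noise fraction may exceed "
            "the abundance of reads true to the actual alleles",
            stacklevel=2,
        )
    return out
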