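"""Pairwise HP linkage (Cramér's V) and artefact-HP exclusion.

True heterozygous positions co-segregate across long reads and are therefore
strongly linked, while sequencing/mapping artefacts are not. Linkage is
measured as Cramér's V over the contingency table of co-occurring base
symbols; the matrix of pairwise linkage values is clustered into two groups
and the low-linkage group is excluded when the groups' mean intra-cluster
linkage differs by more than a set threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from .variants import MISSING, ReadGenotypeMatrix

#: V on tiny contingency tables is unstable; pairs with fewer co-covering
#: reads than this are recorded as missing.
DEFAULT_MIN_PAIR_SUPPORT = 10

#: Exclusion threshold on the gap between the two HP groups' mean
#: intra-cluster linkage: fully linked groups sit near V = 1 while noise
#: groups sit near 0-0.3, so 0.4 separates them without firing on modest
#: allele imbalance.
DEFAULT_MEAN_GAP_THRESHOLD = 0.4


def cramers_v(
    col_i: np.ndarray,
    col_j: np.ndarray,
    min_pair_support: int = DEFAULT_MIN_PAIR_SUPPORT,
) -> Optional[float]:
    """Cramér's V between two genotype columns (base codes, MISSING = -1).

    V = sqrt(chi2 / (n * (min(r, c) - 1))) over the contingency table of
    co-occurring symbols (reads missing either position excluded; all-zero
    rows/columns dropped). No continuity correction: V is a descriptive
    linkage score, not a test. Returns None for insufficient pair support;
    returns 0.0 when either margin is constant.
    """
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    ok = (col_i != MISSING) & (col_j != MISSING)
    n = int(ok.sum())
    if n < min_pair_support:
        return None
    table = pd.crosstab(col_i[ok], col_j[ok]).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    k = min(r, c)
    if k <= 1:
        return 0.0
    chi2 = chi2_contingency(table, correction=False).statistic
    return float(np.sqrt(chi2 / (n * (k - 1))))


@dataclass
class LinkageMatrix:
    """Symmetric matrix of pairwise Cramér's V over HP positions."""

    positions: list[int]
    values: np.ndarray  # (n, n), NaN where support was insufficient
    support: np.ndarray  # (n, n) co-covering read counts

    def __len__(self) -> int:
        return len(self.positions)

    def imputed(self) -> np.ndarray:
        """V matrix with missing entries imputed as 0 (with a warning)."""
        vals = self.values.copy()
        miss = np.isnan(vals)
        if miss.any():
            warnings.warn(
                f"{int(miss.sum()) // 2} HP pairs lack support; "
                "imputing V = 0 for clustering",
                stacklevel=2,
            )
            vals[miss] = 0.0
        return vals

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.positions, columns=self.positions
        ).to_csv(path, sep="\t")


def linkage_matrix(
    m: ReadGenotypeMatrix, min_pair_support: int = DEFAULT_MIN_PAIR_SUPPORT
) -> LinkageMatrix:
    """All-pairs Cramér's V between HP genotype columns."""
    if m.n_hps < 2:
        return LinkageMatrix(
            positions=list(m.positions),
            values=np.ones((m.n_hps, m.n_hps)),
            support=np.full((m.n_hps, m.n_hps), m.n_reads),
        )
    n = m.n_hps
    values = np.eye(n)
    covered = m.codes != MISSING
    support = covered.astype(int).T @ covered.astype(int)
    for i in range(n):
        for j in range(i + 1, n):
            v = cramers_v(m.codes[:, i], m.codes[:, j], min_pair_support)
            values[i, j] = values[j, i] = np.nan if v is None else v
    return LinkageMatrix(positions=list(m.positions), values=values, support=support)


def exclude_artefact_hps(
    lm: LinkageMatrix,
    mean_gap_threshold: float = DEFAULT_MEAN_GAP_THRESHOLD,
) -> tuple[list[int], list[int]]:
    """Two-group linkage clustering of HPs; drop the low-linkage group.

    Hierarchical clustering (Ward criterion) on distance 1 - V, cut into
    exactly two groups; Ward's variance criterion separates a weakly
    self-linked artefact group from the tight true-HP block much more
    reliably than single/average merging. Each group's mean intra-cluster V
    is computed (a singleton group's mean is its mean V to the members of
    the other group, which makes the rule total); if the high-mean group
    exceeds the low-mean group by more than ``mean_gap_threshold``, the low
    group is excluded. The split is repeated on the surviving HPs
    (artefacts sometimes peel off one at a time) until the gap falls below
    the threshold or fewer than three HPs remain.
    """
    n = len(lm)
    if n < 2:
        return list(lm.positions), []
    vals = lm.imputed()

    def group_mean(members: np.ndarray, others: np.ndarray) -> float:
        if len(members) == 1:
            return float(vals[members[0], others].mean())
        sub = vals[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        return float(sub[iu].mean())

    active = np.arange(n)
    excluded_idx: list[int] = []
    while len(active) >= 2:
        sub = vals[np.ix_(active, active)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        Z = _scipy_linkage(squareform(dist, checks=False), method="ward")
        labels = fcluster(Z, t=2, criterion="maxclust")
        g1 = active[labels == 1]
        g2 = active[labels == 2]
        if len(g1) == 0 or len(g2) == 0:  # degenerate: a single cluster
            break
        m1, m2 = group_mean(g1, g2), group_mean(g2, g1)
        if abs(m1 - m2) <= mean_gap_threshold:
            break
        low = g2 if m1 >= m2 else g1
        if len(low) > len(active) / 2:
            # artefacts are the minority; a small group with spuriously
            # inflated linkage (e.g. from low pair support) must not evict
            # the main HP block
            break
        excluded_idx.extend(int(i) for i in low)
        active = np.array(sorted(set(active.tolist()) - set(low.tolist())))
        if len(active) < 3:
            break
    return (
        [lm.positions[i] for i in sorted(active.tolist())],
        [lm.positions[i] for i in sorted(excluded_idx)],
    )
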