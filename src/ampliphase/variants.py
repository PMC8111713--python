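"""Heterozygous-position detection, long-read genotyping and PWM filtering.

Heterozygous positions (HPs) are non-gap reference coordinates where the
short-read pileup shows a second allele above a minor-allele-frequency
threshold (default 0.2). The genotype at each HP is then inferred for every
long read separately, and reads/HPs with insufficient mutual coverage are
discarded (reads must cover at least 90% of HPs, HPs must be covered by at
least 30% of the surviving reads — applied once, in that order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead, BASE_CODE, CODE_BASE, Pileup

#: Paper-stated defaults.
DEFAULT_MAF = 0.2
DEFAULT_MIN_READ_COV = 0.9
DEFAULT_MIN_HP_COV = 0.3

#: Below this short-read depth a 0.2 minor-allele frequency cannot be told
#: apart from sequencing noise; positions this shallow are never HPs.
DEFAULT_MIN_DEPTH = 20


@dataclass
class HPSet:
    """Sorted heterozygous-position coordinates with allele frequencies.

    ``allele_freqs[i]`` is the frequency vector over {A, C, G, T} at
    ``positions[i]``, computed over non-deletion depth. Third alleles above
    the threshold are reported (``extra_alleles``) but only the top two are
    carried into clustering.
    """

    positions: list[int]
    allele_freqs: np.ndarray  # (n_hps, 4)
    maf_threshold: float = DEFAULT_MAF
    extra_alleles: list[tuple[int, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    def top_two(self) -> list[tuple[str, str]]:
        """Major and minor allele per HP."""
        order = np.argsort(self.allele_freqs, axis=1)
        return [
            (CODE_BASE[order[i, 3]], CODE_BASE[order[i, 2]])
            for i in range(len(self.positions))
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.allele_freqs, columns=list("ACGT"), index=self.positions
        )
        df.index.name = "position"
        return df

    def to_bed(self, path, name: str = "HP") -> None:
        """0-based, half-open BED of HP coordinates."""
        with open(path, "wt") as out:
            for p in self.positions:
                out.write(f"{name}\t{p}\t{p + 1}\n")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def detect_hps(
    short_pileup: Pileup,
    maf: float = DEFAULT_MAF,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> HPSet:
    """Detect non-gap heterozygous positions from the short-read pileup.

    A position qualifies when, among non-deletion counts at depth >=
    ``min_depth``, the second most frequent base reaches frequency >= ``maf``.
    Deletions are never counted as alleles; deletion-dominated positions
    surface later as indel problem positions instead.
    """
    if not 0 < maf < 0.5:
        raise ValueError("maf must be in (0, 0.5)")
    base_counts = short_pileup.counts[:, :4].astype(float)
    nondel_depth = base_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(nondel_depth[:, None] > 0, base_counts / np.maximum(nondel_depth, 1)[:, None], 0.0)
    sorted_freqs = np.sort(freqs, axis=1)
    second = sorted_freqs[:, 2]
    third = sorted_freqs[:, 1]
    is_hp = (nondel_depth >= min_depth) & (second >= maf)
    positions = np.nonzero(is_hp)[0]
    extra = []
    order = np.argsort(freqs, axis=1)
    for p in positions:
        if third[p] >= maf:
            extra.append((int(p), CODE_BASE[order[p, 1]], float(third[p])))
    return HPSet(
        positions=[int(p) for p in positions],
        allele_freqs=freqs[positions],
        maf_threshold=maf,
        extra_alleles=extra,
    )


MISSING = -1  # genotype code for "no base": deletion, N or no coverage


@dataclass
class ReadGenotypeMatrix:
    """reads x HPs genotype matrix.

    ``codes[i, j]`` is the base code (0-3) of read *i* at HP *j*, or
    ``MISSING`` when the read's alignment places no base (or a deletion)
    there.
    """

    read_ids: list[str]
    positions: list[int]
    codes: np.ndarray  # (n_reads, n_hps) int8

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_hps(self) -> int:
        return len(self.positions)

    def read_coverage(self) -> np.ndarray:
        """Fraction of HPs covered, per read."""
        if self.n_hps == 0:
            return np.zeros(self.n_reads)
        return (self.codes != MISSING).mean(axis=1)

    def hp_coverage(self) -> np.ndarray:
        """Fraction of reads covering each HP."""
        if self.n_reads == 0:
            return np.zeros(self.n_hps)
        return (self.codes != MISSING).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        sym = np.full(self.codes.shape, ".", dtype="<U1")
        for c in range(4):
            sym[self.codes == c] = CODE_BASE[c]
        return pd.DataFrame(sym, index=self.read_ids, columns=self.positions)

    def select(self, read_mask: np.ndarray, hp_mask: np.ndarray) -> "ReadGenotypeMatrix":
        return ReadGenotypeMatrix(
            read_ids=[r for r, m in zip(self.read_ids, read_mask) if m],
            positions=[p for p, m in zip(self.positions, hp_mask) if m],
            codes=self.codes[np.asarray(read_mask)][:, np.asarray(hp_mask)],
        )


#: Half-width of the window realigned around each HP when genotyping.
REALIGN_WINDOW = 12


def _ref_to_query(aln: AlignedRead) -> np.ndarray:
    """Query index per reference position of the alignment span (-1 where
    the reference base is deleted from the read)."""
    out = np.full(aln.ref_span, -1, dtype=np.int64)
    q = aln.query_start
    r = 0
    for kind, length, _ in aln.ops:
        if kind in ("match", "mismatch"):
            out[r : r + length] = np.arange(q, q + length)
            q += length
            r += length
        elif kind == "del":
            r += length
        else:  # ins
            q += length
    return out


def _realign_aligner():
    from Bio import Align

    return Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-4,
        open_gap_score=-4,
        extend_gap_score=-1,
    )


def _genotype_by_realignment(
    aln: AlignedRead,
    ref_bases: str,
    positions: np.ndarray,
    window: int,
    pairwise,
) -> np.ndarray:
    """Base code per HP for one read via local affine realignment.

    Whole-read edit-distance alignments place bases near indel errors
    ambiguously; realigning a small window anchored around each HP with
    affine gap scores recovers the base-to-column correspondence the way a
    variant caller's local realignment does.
    """
    out = np.full(len(positions), MISSING, dtype=np.int8)
    r2q = _ref_to_query(aln)
    qseq = aln.aligned_bases()
    L = len(ref_bases)
    for j, p in enumerate(positions):
        lo = max(0, p - window)
        hi = min(L, p + window + 1)
        if lo < aln.ref_offset or hi > aln.ref_end:
            continue
        seg = r2q[lo - aln.ref_offset : hi - aln.ref_offset]
        covered = seg[seg >= 0]
        if len(covered) == 0:
            continue
        sub = qseq[covered.min() : covered.max() + 1]
        if not sub:
            continue
        center = p - lo
        target_blocks, query_blocks = pairwise.align(
            ref_bases[lo:hi], sub
        )[0].aligned
        base = None
        for (ts, te), (qs, _qe) in zip(target_blocks, query_blocks):
            if ts <= center < te:
                base = sub[qs + (center - ts)]
                break
        if base is not None:
            code = BASE_CODE.get(base)
            if code is not None:
                out[j] = code
    return out


def genotype_reads(
    long_alignments: Sequence[AlignedRead],
    hps: HPSet,
    reference_bases: Optional[str] = None,
    realign: bool = True,
    window: int = REALIGN_WINDOW,
) -> ReadGenotypeMatrix:
    """Infer the genotype at each HP for each long read separately.

    By default each HP is genotyped by realigning a small read window
    around it with affine gap scores (requires ``reference_bases``); with
    ``realign=False`` (or without the reference) the base is taken directly
    from the whole-read alignment column.
    """
    if len(hps) == 0:
        raise ValueError(
            "nothing to phase: no heterozygous positions (homozygous sample?)"
        )
    positions = np.asarray(hps.positions)
    codes = np.full((len(long_alignments), len(positions)), MISSING, dtype=np.int8)
    do_realign = realign and reference_bases is not None
    pairwise = _realign_aligner() if do_realign else None
    for i, aln in enumerate(long_alignments):
        if do_realign:
            codes[i] = _genotype_by_realignment(
                aln, reference_bases, positions, window, pairwise
            )
        else:
            vals = aln.base_at(positions)
            ok = (vals >= 0) & (vals <= 3)  # del (4), N (-1), uncovered (-2)
            codes[i, ok] = vals[ok]
    return ReadGenotypeMatrix(
        read_ids=[a.read.id for a in long_alignments],
        positions=[int(p) for p in positions],
        codes=codes,
    )


def filter_genotype_matrix(
    m: ReadGenotypeMatrix,
    min_read_cov: float = DEFAULT_MIN_READ_COV,
    min_hp_cov: float = DEFAULT_MIN_HP_COV,
) -> ReadGenotypeMatrix:
    """Discard long reads covering < 90% of HPs, then HPs covered by < 30% of
    the surviving reads. Each filter is applied exactly once, in that order
    (removing reads can only lower HP coverage, so the order matters)."""
    if not (0 < min_read_cov <= 1 and 0 < min_hp_cov <= 1):
        raise ValueError("coverage thresholds must be in (0, 1]")
    read_keep = m.read_coverage() >= min_read_cov
    if not read_keep.any():
        cov = m.read_coverage()
        raise ValueError(
            "all long reads removed by the HP-coverage filter "
            f"(coverage min/median/max = {cov.min():.2f}/"
            f"{np.median(cov):.2f}/{cov.max():.2f})"
        )
    surviving = m.select(read_keep, np.ones(m.n_hps, dtype=bool))
    hp_keep = surviving.hp_coverage() >= min_hp_cov
    return surviving.select(np.ones(surviving.n_reads, dtype=bool), hp_keep)


@dataclass
class PWM:
    """Per-position frequency vectors over {A, C, G, T, del}.

    Zero-depth columns are flagged uninformative and excluded from scoring.
    """

    freqs: np.ndarray  # (L, 5)
    informative: np.ndarray  # (L,) bool

    def __len__(self) -> int:
        return len(self.freqs)


def pwm_from_pileup(p: Pileup) -> PWM:
    counts = p.counts.astype(float)
    depth = counts.sum(axis=1)
    informative = depth > 0
    freqs = np.zeros_like(counts)
    freqs[informative] = counts[informative] / depth[informative, None]
    return PWM(freqs=freqs, informative=informative)


def score_read_against_pwm(aln: AlignedRead, pwm: PWM) -> float:
    """Mean PWM frequency of the read's base over informative aligned
    positions (deletions scored by the deletion frequency)."""
    positions, codes, _ = aln.column_codes()
    ok = (codes >= 0) & (positions < len(pwm.freqs))
    positions, codes = positions[ok], codes[ok]
    ok = pwm.informative[positions]
    positions, codes = positions[ok], codes[ok]
    if len(positions) == 0:
        return 0.0
    return float(pwm.freqs[positions, codes].mean())


def filter_longreads_by_pwm(
    long_alignments: Sequence[AlignedRead],
    pwm: Optional[PWM],
    min_score: Optional[float] = None,
) -> list[AlignedRead]:
    """Optional low-quality long-read winnowing: read quality is similarity
    to the PWM derived from the same mapping. Disabled when ``min_score`` is
    None (input returned unchanged)."""
    alignments = list(long_alignments)
    if pwm is None or min_score is None:
        return alignments
    if not 0 < min_score < 1:
        raise ValueError("min_score must be in (0, 1)")
    return [a for a in alignments if score_read_against_pwm(a, pwm) >= min_score]
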