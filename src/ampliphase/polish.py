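"""Short-read polishing of haplotype drafts and residual-problem reporting.

Short reads are partitioned by haplotype (majority vote over the
heterozygous positions they cover; reads covering none are distributed to
all haplotypes), mapped to the long-read-derived draft references, and the
final consensus is called from these mappings. Residual heterozygosity,
unresolved insertions, deletion signals and homopolymer inconsistencies are
flagged for manual review rather than silently auto-resolved.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .align import AlignedRead, build_pileup, map_reads
from .consensus import ConsensusResult, call_consensus
from .seqio import ReadSet, ReferenceSeq, SHORT
from .variants import HPSet, MISSING

#: Homopolymer runs at least this long get a per-read length-mode check.
DEFAULT_MIN_HP_LEN = 8

#: Sub-majority deletion/insertion signals above this fraction of local
#: depth are reported as problems (they do not change the sequence).
PROBLEM_MIN_FRAC = 0.2

PROBLEM_KINDS = (
    "residual_heterozygosity",
    "unresolved_insertion",
    "deletion_signal",
    "homopolymer_mismatch",
)


@dataclass
class Problem:
    """A flagged position in a haplotype's final mapping."""

    position: int
    kind: str
    detail: dict = field(default_factory=dict)

    @property
    def blocking(self) -> bool:
        """Whether the problem leaves the sequence ambiguous or altered
        (sub-majority deletion/insertion signals are informational)."""
        if self.kind == "deletion_signal":
            return bool(self.detail.get("dropped", False))
        return True

    def to_dict(self) -> dict:
        return {"position": self.position, "kind": self.kind, **self.detail}


@dataclass
class PartitionResult:
    """Short reads split by haplotype cluster.

    ``unique_by_cluster`` holds the ids of reads assigned to exactly one
    cluster by the HP vote — the *clustered* short reads carrying genuine
    haplotype evidence, as opposed to HP-free or tied reads distributed to
    all clusters."""

    by_cluster: dict[int, list[AlignedRead]]
    unique_by_cluster: dict[int, set] = field(default_factory=dict)
    ambiguous_reads: list[str] = field(default_factory=list)
    hp_free_count: int = 0


def partition_short_reads(
    short_alignments: Sequence[AlignedRead],
    hps: HPSet,
    cluster_hp_genotypes: dict[int, np.ndarray],
) -> PartitionResult:
    """Assign each short read to the haplotype cluster whose HP genotype it
    matches at the majority of the HPs it covers.

    Ties are distributed to all tied clusters (and counted as ambiguous);
    reads covering no HP are copied into every cluster's set, so every input
    read appears in at least one partition.
    """
    if len(hps) == 0:
        raise ValueError("cannot partition short reads without HPs")
    positions = np.asarray(hps.positions)
    cluster_ids = sorted(cluster_hp_genotypes)
    # consensus allele (base code) per cluster per HP
    alleles = {c: cluster_hp_genotypes[c].argmax(axis=1) for c in cluster_ids}
    informative = {c: cluster_hp_genotypes[c].sum(axis=1) > 0 for c in cluster_ids}
    out: dict[int, list[AlignedRead]] = {c: [] for c in cluster_ids}
    unique: dict[int, set] = {c: set() for c in cluster_ids}
    ambiguous: list[str] = []
    hp_free = 0
    for aln in short_alignments:
        codes = aln.base_at(positions)
        covered = (codes >= 0) & (codes <= 3)
        if not covered.any():
            hp_free += 1
            for c in cluster_ids:
                out[c].append(aln)
            continue
        votes = {
            c: int(
                np.sum((codes == alleles[c]) & covered & informative[c])
            )
            for c in cluster_ids
        }
        best = max(votes.values())
        winners = [c for c in cluster_ids if votes[c] == best]
        if len(winners) > 1:
            ambiguous.append(aln.read.id)
        else:
            unique[winners[0]].add(aln.read.id)
        for c in winners:
            out[c].append(aln)
    return PartitionResult(
        by_cluster=out, unique_by_cluster=unique,
        ambiguous_reads=ambiguous, hp_free_count=hp_free,
    )


@dataclass
class HomopolymerRun:
    position: int  # start in the final sequence (0-based)
    base: str
    consensus_length: int
    histogram: dict[int, int]
    mode_length: Optional[int]
    consistent: Optional[bool]
    checkable: bool

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "base": self.base,
            "consensus_length": self.consensus_length,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "mode_length": self.mode_length,
            "consistent": self.consistent,
            "checkable": self.checkable,
        }


@dataclass
class HomopolymerReport:
    runs: list[HomopolymerRun] = field(default_factory=list)

    def problems(self) -> list[Problem]:
        out = []
        for r in self.runs:
            if r.checkable and not r.consistent:
                out.append(
                    Problem(
                        r.position,
                        "homopolymer_mismatch",
                        {
                            "base": r.base,
                            "consensus_length": r.consensus_length,
                            "mode_length": r.mode_length,
                        },
                    )
                )
        return out


def _ref_to_query_map(aln: AlignedRead) -> np.ndarray:
    """Query index for each reference position in the alignment span
    (-1 where the reference base is deleted from the read)."""
    span = aln.ref_span
    out = np.full(span, -1, dtype=np.int64)
    q = aln.query_start
    r = 0
    for kind, length, _ in aln.ops:
        if kind in ("match", "mismatch"):
            out[r : r + length] = np.arange(q, q + length)
            q += length
            r += length
        elif kind == "del":
            r += length
        elif kind == "ins":
            q += length
    return out


def run_length_counts(
    alignments: Sequence[AlignedRead], start: int, end: int, base: str
) -> Counter:
    """Per-read length histogram for the reference run [start, end).

    Each read fully spanning the run plus one anchor base on each side
    contributes the count of the run base between its anchor-aligned
    positions."""
    hist: Counter = Counter()
    for aln in alignments:
        if aln.ref_offset > start - 1 or aln.ref_end < end + 1:
            continue
        r2q = _ref_to_query_map(aln)
        q1 = r2q[start - 1 - aln.ref_offset]
        q2 = r2q[end - aln.ref_offset]
        if q1 < 0 or q2 < 0:
            continue
        hist[aln.aligned_bases()[q1 + 1 : q2].count(base)] += 1
    return hist


def long_read_indel_rates(alignments: Sequence[AlignedRead]) -> tuple[float, float, float]:
    """Empirical per-base (substitution, insertion, deletion) rates of a set
    of long-read alignments, from their edit-operation statistics."""
    n_match = n_mis = n_ins = n_del = 0
    for aln in alignments:
        for kind, length, _ in aln.ops:
            if kind == "match":
                n_match += length
            elif kind == "mismatch":
                n_mis += length
            elif kind == "ins":
                n_ins += length
            else:
                n_del += length
    aligned = max(n_match + n_mis + n_del, 1)
    return n_mis / aligned, n_ins / aligned, n_del / aligned


@dataclass
class RunResolution:
    """How one homopolymer run's length was settled."""

    position: int  # start in the (input) draft
    base: str
    draft_length: int
    resolved_length: int
    method: str  # short_unique | long_corrected | short_all | unresolved
    detail: dict = field(default_factory=dict)


def _mode(hist: Counter, anchor_len: int) -> int:
    top = max(hist.values())
    return sorted(
        (k for k, v in hist.items() if v == top),
        key=lambda k: (abs(k - anchor_len), k),
    )[0]


def _run_indel_signals(pile, s: int, e: int, base: str) -> tuple[float, float, float]:
    """Evidence for a length change of the run [s, e): fraction of reads
    inserting extra copies of the run base near the run, the share of the
    dominant inserted length among those, and the maximum deletion fraction
    inside the run."""
    depth = pile.depth
    ins_count = 0
    by_len: Counter = Counter()
    local_depth = 0
    for p in range(max(0, s - 2), min(pile.ref_length, e + 1)):
        ctr = pile.insertions.get(p)
        if not ctr:
            continue
        for seq, n in ctr.items():
            if set(seq) == {base}:
                ins_count += n
                by_len[len(seq)] += n
        local_depth = max(local_depth, int(depth[p]))
    if local_depth == 0:
        local_depth = max(int(depth[max(0, s - 1) : e].max(initial=0)), 1)
    f_plus = ins_count / local_depth
    top_share = (max(by_len.values()) / ins_count) if ins_count else 1.0
    span_depth = depth[s:e]
    dels = pile.counts[s:e, 4]
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(span_depth > 0, dels / np.maximum(span_depth, 1), 0.0)
    f_minus = float(fr.max()) if len(fr) else 0.0
    return f_plus, top_share, f_minus


def resolve_homopolymer_lengths(
    draft: ReferenceSeq,
    short_alignments: Sequence[AlignedRead],
    pile,
    unique_ids: Optional[set],
    long_alignments: Optional[Sequence[AlignedRead]],
    min_run: int = 6,
    min_unique: int = 5,
    min_long: int = 10,
    amb_lo: float = 0.3,
    amb_hi: float = 0.7,
) -> list[RunResolution]:
    """Settle the length of long homopolymer runs whose short-read indel
    evidence is ambiguous.

    HP-free short reads are distributed to both haplotypes, so a one-unit
    homopolymer length difference far from any heterozygous position leaves
    the insertion/deletion evidence at a run near 50:50 — a coin flip for
    column-wise consensus (decisive evidence away from that zone is left to
    the ordinary majority call). For such runs the length is decided by the
    best haplotype-specific evidence available, in order:

    1. the length mode over *uniquely assigned* short reads spanning the run
       (short reads carry essentially exact run lengths);
    2. the bias-corrected mean over this haplotype's retained long reads:
       observed run-base counts shrink with the substitution and deletion
       rates and grow with a quarter of the insertion rate, so
       ``length ~= mean_count / (1 - p_del - p_sub + p_ins / 4)``;
    3. leave the run unchanged and flag it.

    Returns the resolutions (positions in input-draft coordinates); only
    runs listed as resolved are meant to be edited in and protected from
    column-wise indel calls afterwards.
    """
    resolutions: list[RunResolution] = []
    p_rates = (
        long_read_indel_rates(long_alignments) if long_alignments else None
    )
    for m in re.finditer(r"(.)\1{%d,}" % (min_run - 1), draft.bases):
        s, e = m.start(), m.end()
        base = m.group(1)
        if s == 0 or e == len(draft.bases):
            continue
        cons_len = e - s
        f_plus, top_share, f_minus = _run_indel_signals(pile, s, e, base)
        ambiguous = (
            amb_lo <= f_plus <= amb_hi
            or amb_lo <= f_minus <= amb_hi
            or (f_plus > amb_hi and top_share < amb_hi)
        )
        if not ambiguous:
            continue
        detail: dict = {
            "ins_fraction": round(f_plus, 3),
            "del_fraction": round(f_minus, 3),
        }
        target: Optional[int] = None
        method = "unresolved"
        if unique_ids:
            hist_unique = run_length_counts(
                [a for a in short_alignments if a.read.id in unique_ids],
                s, e, base,
            )
            if sum(hist_unique.values()) >= min_unique:
                target = _mode(hist_unique, cons_len)
                method = "short_unique"
                detail["n_reads"] = sum(hist_unique.values())
        if target is None and long_alignments:
            hist_long = run_length_counts(long_alignments, s, e, base)
            n = sum(hist_long.values())
            if n >= min_long:
                p_sub, p_ins, p_del = p_rates
                c = max(1.0 - p_del - p_sub + p_ins / 4.0, 0.5)
                mean_obs = sum(k * v for k, v in hist_long.items()) / n
                est = mean_obs / c
                target = int(round(est))
                method = "long_corrected"
                detail.update(n_reads=n, estimate=round(est, 2))
        if target is None or target < 1:
            resolutions.append(
                RunResolution(s, base, cons_len, cons_len, "unresolved", detail)
            )
            continue
        resolutions.append(RunResolution(s, base, cons_len, target, method, detail))
    return resolutions


def homopolymer_check(
    alignments: Sequence[AlignedRead],
    final: ReferenceSeq,
    min_hp_len: int = DEFAULT_MIN_HP_LEN,
    prefer_ids: Optional[set] = None,
) -> HomopolymerReport:
    """Compare each long homopolymer's consensus length with the per-read
    length mode.

    For every maximal single-base run of length >= ``min_hp_len`` in the
    final sequence, each read fully spanning the run plus one anchor base on
    each side contributes its own run length (the count of the run base
    between the anchors). The mode of the histogram (ties broken toward the
    consensus length, then smaller) must equal the consensus length for the
    run to be consistent; runs without spanning reads are uncheckable.
    """
    if min_hp_len < 3:
        raise ValueError("min_hp_len must be >= 3")
    report = HomopolymerReport()
    for m in re.finditer(r"(.)\1{%d,}" % (min_hp_len - 1), final.bases):
        s, e = m.start(), m.end()
        base = m.group(1)
        if s == 0 or e == len(final.bases):
            continue  # no anchor base on one side
        hist = run_length_counts(alignments, s, e, base)
        if prefer_ids:
            preferred = run_length_counts(
                [a for a in alignments if a.read.id in prefer_ids], s, e, base
            )
            if sum(preferred.values()) >= 5:
                hist = preferred
        cons_len = e - s
        if not hist:
            report.runs.append(
                HomopolymerRun(s, base, cons_len, {}, None, None, checkable=False)
            )
            continue
        mode = _mode(hist, cons_len)
        report.runs.append(
            HomopolymerRun(
                s, base, cons_len, dict(hist), mode, mode == cons_len, checkable=True
            )
        )
    return report


@dataclass
class HaplotypeResult:
    """Final outcome for one haplotype."""

    haplotype_id: str
    draft_sequence: str
    final_sequence: str
    problem_positions: list[Problem] = field(default_factory=list)
    short_read_count: int = 0
    long_read_count: int = 0
    unpolished: bool = False
    consensus: Optional[ConsensusResult] = None
    final_alignments: Optional[list] = None

    @property
    def blocking_problems(self) -> list[Problem]:
        return [p for p in self.problem_positions if p.blocking]


def _mapping_problems(
    pileup, result: ConsensusResult, problem_min_frac: float = PROBLEM_MIN_FRAC
) -> list[Problem]:
    """Problem positions of a consensus call: residual heterozygosity,
    deletion signals (dropped or sub-majority) and unresolved insertions."""
    problems: list[Problem] = []
    for pos, code, freqs in result.ambiguous_positions:
        problems.append(
            Problem(pos, "residual_heterozygosity", {"code": code, "freqs": freqs})
        )
    depth = pileup.depth
    del_frac = np.zeros(pileup.ref_length)
    nz = depth > 0
    del_frac[nz] = pileup.counts[nz, 4] / depth[nz]
    dropped = set(result.dropped_positions)
    # contiguous sub-majority deletion signals (e.g. reads shared across a
    # structural-deletion junction) collapse into one flagged interval
    signal = sorted(int(p) for p in np.nonzero(del_frac >= problem_min_frac)[0])
    run_start = None
    prev = None
    for pos in signal + [None]:
        if run_start is not None and (pos is None or pos != prev + 1
                                      or (pos in dropped) != (prev in dropped)):
            frac = float(del_frac[run_start : prev + 1].max())
            problems.append(
                Problem(
                    run_start,
                    "deletion_signal",
                    {
                        "end": prev + 1,
                        "fraction": frac,
                        "dropped": run_start in dropped,
                    },
                )
            )
            run_start = None
        if pos is not None and run_start is None:
            run_start = pos
        prev = pos
    for pos, ctr in result.conflicting_insertions:
        problems.append(Problem(pos, "unresolved_insertion", {"alleles": ctr}))
    spliced = {p for p, _ in result.spliced_insertions}
    for pos, ctr in pileup.insertions.items():
        if pos in spliced:
            continue
        d = depth[pos] if pos < len(depth) else 0
        if d > 0:
            frac = sum(ctr.values()) / d
            if problem_min_frac <= frac <= 0.5:
                problems.append(
                    Problem(
                        int(pos),
                        "unresolved_insertion",
                        {"fraction": float(frac), "alleles": dict(ctr)},
                    )
                )
    problems.sort(key=lambda p: p.position)
    return problems


def polish_haplotype(
    short_set: ReadSet,
    draft: ReferenceSeq,
    tie_ratio: float = 0.75,
    min_depth: int = 3,
    long_read_count: int = 0,
    long_alignments: Optional[Sequence[AlignedRead]] = None,
    unique_ids: Optional[set] = None,
    hp_aware_min_run: int = 6,
    mapper: Callable = map_reads,
) -> HaplotypeResult:
    """Polish a long-read draft into the final haplotype consensus using the
    haplotype's short reads; with zero short reads (long-read-only mode) the
    draft is returned unchanged and flagged unpolished.

    Homopolymer runs of at least ``hp_aware_min_run`` bases are settled by
    the run-length resolver (see :func:`resolve_homopolymer_lengths`) and
    protected from column-wise indel calls; resolutions that fall back to
    low-confidence evidence surface as problems via the homopolymer check.
    """
    if len(short_set) == 0:
        result = HaplotypeResult(
            haplotype_id=draft.id,
            draft_sequence=draft.bases,
            final_sequence=draft.bases,
            problem_positions=[],
            short_read_count=0,
            long_read_count=long_read_count,
            unpolished=True,
        )
        return result
    current = draft
    long_reads = [a.read for a in long_alignments] if long_alignments else None
    result: Optional[HaplotypeResult] = None
    for _pass in range(3):
        alignments = mapper(short_set, current)
        pile = build_pileup(alignments, len(current.bases))
        resolutions: list[RunResolution] = []
        if hp_aware_min_run:
            la = long_alignments
            if _pass > 0 and long_reads:
                la = mapper(long_reads, current)
            resolutions = resolve_homopolymer_lengths(
                current, alignments, pile, unique_ids, la,
                min_run=hp_aware_min_run,
            )
        result = _finish_polish(
            short_set, current, alignments, pile, resolutions,
            tie_ratio, min_depth, long_read_count, mapper,
        )
        # iterate until the consensus is a fixed point of its own mapping
        # (resolves e.g. uncalled N tails the previous draft repelled)
        if result.final_sequence == result.draft_sequence:
            break
        current = ReferenceSeq(draft.id, result.final_sequence)
    assert result is not None
    return result


def _finish_polish(
    short_set: ReadSet,
    draft: ReferenceSeq,
    alignments: list,
    pile,
    resolutions: Sequence[RunResolution],
    tie_ratio: float,
    min_depth: int,
    long_read_count: int,
    mapper: Callable,
) -> HaplotypeResult:
    """Apply run resolutions to a draft, call the final consensus with the
    resolved runs protected, and assemble the problem report."""
    edits = [
        (r.position, r.position + r.draft_length, r.base * r.resolved_length)
        for r in resolutions
        if r.method != "unresolved" and r.resolved_length != r.draft_length
    ]
    if edits:
        bases = draft.bases
        for s, e, rep in sorted(edits, reverse=True):
            bases = bases[:s] + rep + bases[e:]
        draft = ReferenceSeq(draft.id, bases)
        alignments = mapper(short_set, draft)
        pile = build_pileup(alignments, len(draft.bases))
    no_indel = np.zeros(len(draft.bases), dtype=bool)
    offset = 0
    resolved = [r for r in resolutions if r.method != "unresolved"]
    for r in sorted(resolutions, key=lambda x: x.position):
        s = r.position + offset
        if r.method != "unresolved":
            no_indel[max(0, s - 2) : s + r.resolved_length + 1] = True
        offset += r.resolved_length - r.draft_length
    result = call_consensus(
        pile, tie_ratio=tie_ratio, min_depth=min_depth,
        no_indel=no_indel if resolved else None,
    )
    problems = _mapping_problems(pile, result)
    for r in resolutions:
        if r.method == "unresolved":
            problems.append(
                Problem(r.position, "homopolymer_mismatch",
                        {"base": r.base, "consensus_length": r.draft_length,
                         "mode_length": None,
                         "note": "ambiguous, no deciding evidence", **r.detail})
            )
        elif r.method.startswith("long_"):
            # settled from statistical long-read evidence, not exact
            # short-read counts: worth a manual look
            problems.append(
                Problem(r.position, "homopolymer_mismatch",
                        {"base": r.base, "consensus_length": r.resolved_length,
                         "mode_length": None, "method": r.method,
                         "note": "resolved from long-read run-length statistics",
                         **r.detail})
            )
    return HaplotypeResult(
        haplotype_id=draft.id,
        draft_sequence=draft.bases,
        final_sequence=result.sequence,
        problem_positions=problems,
        short_read_count=len(short_set),
        long_read_count=long_read_count,
        consensus=result,
        final_alignments=alignments,
    )


def _ambiguous_runs(draft, pile, min_run, amb_lo=0.3, amb_hi=0.7):
    """Homopolymer runs whose indel evidence sits in the ambiguous zone."""
    out = []
    for m in re.finditer(r"(.)\1{%d,}" % (min_run - 1), draft.bases):
        s, e = m.start(), m.end()
        base = m.group(1)
        if s == 0 or e == len(draft.bases):
            continue
        f_plus, top_share, f_minus = _run_indel_signals(pile, s, e, base)
        if (
            amb_lo <= f_plus <= amb_hi
            or amb_lo <= f_minus <= amb_hi
            or (f_plus > amb_hi and top_share < amb_hi)
        ):
            out.append((s, e, base, f_plus, f_minus))
    return out


def polish_haplotype_pair(
    short_sets: dict[str, ReadSet],
    drafts: dict[str, ReferenceSeq],
    unique_ids: dict[str, set],
    long_alignments: dict[str, Sequence[AlignedRead]],
    tie_ratio: float = 0.75,
    min_depth: int = 3,
    long_read_counts: Optional[dict[str, int]] = None,
    hp_aware_min_run: int = 6,
    min_unique: int = 5,
    mapper: Callable = map_reads,
) -> dict[str, HaplotypeResult]:
    """Polish two haplotypes jointly, arbitrating ambiguous homopolymers.

    A homopolymer length difference between the haplotypes that lies far
    from every heterozygous position gives each haplotype ~50:50 short-read
    indel evidence (distributed reads are shared), so the decision is made
    jointly: the union of spanning short reads (each read counted once)
    gives the candidate length pair; a haplotype with enough uniquely
    assigned spanning reads takes their mode; its sister then takes the
    remaining candidate; with no unique evidence the haplotype whose
    retained long reads have the larger mean run length takes the longer
    candidate. Runs that remain undecidable are left unchanged and flagged.
    """
    names = sorted(drafts)
    assert len(names) == 2, "joint polishing is defined for exactly two haplotypes"
    current = dict(drafts)
    long_reads = {
        n: [a.read for a in (long_alignments.get(n) or [])] for n in names
    }
    out: dict[str, HaplotypeResult] = {}
    for _pass in range(3):
        long_alns = {
            n: (long_alignments.get(n) if _pass == 0 else mapper(long_reads[n], current[n]))
            for n in names
        }
        out = _polish_pair_once(
            short_sets, current, unique_ids, long_alns, tie_ratio, min_depth,
            long_read_counts, hp_aware_min_run, min_unique, mapper,
        )
        if all(out[n].final_sequence == out[n].draft_sequence for n in names):
            break
        current = {
            n: ReferenceSeq(n, out[n].final_sequence) for n in names
        }
    return out


def _polish_pair_once(
    short_sets, drafts, unique_ids, long_alignments, tie_ratio, min_depth,
    long_read_counts, hp_aware_min_run, min_unique, mapper,
) -> dict[str, HaplotypeResult]:
    names = sorted(drafts)
    state: dict[str, dict] = {}
    for n in names:
        alns = mapper(short_sets[n], drafts[n])
        pile = build_pileup(alns, len(drafts[n].bases))
        state[n] = {
            "alns": alns,
            "pile": pile,
            "runs": _ambiguous_runs(drafts[n], pile, hp_aware_min_run),
            "resolutions": [],
        }

    def span_counts_by_id(alignments, s, e, base):
        counts = {}
        for aln in alignments:
            if aln.ref_offset > s - 1 or aln.ref_end < e + 1:
                continue
            r2q = _ref_to_query_map(aln)
            q1 = r2q[s - 1 - aln.ref_offset]
            q2 = r2q[e - aln.ref_offset]
            if q1 < 0 or q2 < 0:
                continue
            counts[aln.read.id] = aln.aligned_bases()[q1 + 1 : q2].count(base)
        return counts

    def homologous_run(other: str, s: int, base: str):
        cands = [r for r in state[other]["runs"] if r[2] == base and abs(r[0] - s) <= 200]
        if cands:
            return min(cands, key=lambda r: abs(r[0] - s))
        return None

    pending: dict[str, list] = {n: [] for n in names}
    for n in names:
        other = names[1] if n == names[0] else names[0]
        for (s, e, base, f_plus, f_minus) in state[n]["runs"]:
            detail = {"ins_fraction": round(f_plus, 3), "del_fraction": round(f_minus, 3)}
            own = span_counts_by_id(state[n]["alns"], s, e, base)
            uniq = Counter(v for k, v in own.items() if k in (unique_ids.get(n) or set()))
            if sum(uniq.values()) >= min_unique:
                target = _mode(uniq, e - s)
                state[n]["resolutions"].append(
                    RunResolution(s, base, e - s, target, "short_unique",
                                  {**detail, "n_reads": sum(uniq.values())})
                )
            else:
                pending[n].append((s, e, base, own, detail))
    for n in names:
        other = names[1] if n == names[0] else names[0]
        for (s, e, base, own, detail) in pending[n]:
            cons_len = e - s
            partner = homologous_run(other, s, base)
            union = dict(own)
            if partner is not None:
                union.update(
                    span_counts_by_id(state[other]["alns"], partner[0], partner[1], base)
                )
            hist = Counter(union.values())
            target: Optional[int] = None
            method = "unresolved"
            if hist:
                common = hist.most_common()
                L1 = common[0][0]
                bimodal = len(common) > 1 and common[1][1] >= 0.2 * sum(hist.values())
                L2 = common[1][0] if bimodal else L1
                if not bimodal:
                    target, method = L1, "short_all"
                else:
                    # sister settled by unique evidence -> take the other length
                    sister = next(
                        (r for r in state[other]["resolutions"]
                         if r.base == base and abs(r.position - s) <= 200
                         and r.method == "short_unique"),
                        None,
                    )
                    if sister is not None and sister.resolved_length in (L1, L2):
                        target = L2 if sister.resolved_length == L1 else L1
                        method = "cross_elimination"
                    else:
                        own_long = run_length_counts(
                            long_alignments.get(n) or [], s, e, base
                        )
                        partner_long = (
                            run_length_counts(
                                long_alignments.get(other) or [],
                                partner[0], partner[1], base,
                            )
                            if partner is not None
                            else Counter()
                        )
                        n1, n2 = sum(own_long.values()), sum(partner_long.values())
                        if n1 >= 3 and n2 >= 3:
                            m1 = sum(k * v for k, v in own_long.items()) / n1
                            m2 = sum(k * v for k, v in partner_long.items()) / n2
                            # the sign of the mean difference assigns the
                            # longer candidate; a weak margin is still the
                            # best available evidence (leaving a bimodal run
                            # undecided guarantees one haplotype wrong) but
                            # is flagged as low confidence
                            hi, lo = max(L1, L2), min(L1, L2)
                            target = hi if m1 >= m2 else lo
                            method = (
                                "long_mean_diff"
                                if abs(m1 - m2) >= 0.3
                                else "long_mean_diff_weak"
                            )
                            detail.update(
                                own_mean=round(m1, 2), sister_mean=round(m2, 2)
                            )
            if target is None:
                state[n]["resolutions"].append(
                    RunResolution(s, base, cons_len, cons_len, "unresolved", detail)
                )
            else:
                state[n]["resolutions"].append(
                    RunResolution(s, base, cons_len, target, method, detail)
                )
    out = {}
    for n in names:
        out[n] = _finish_polish(
            short_sets[n], drafts[n], state[n]["alns"], state[n]["pile"],
            state[n]["resolutions"], tie_ratio, min_depth,
            (long_read_counts or {}).get(n, 0), mapper,
        )
    return out


@dataclass
class VerificationReport:
    """Re-mapping report for a (possibly manually edited) haplotype
    reference; read composition is frozen, no re-clustering happens."""

    haplotype_id: str
    problems: list[Problem]
    consensus_mismatches: list[tuple[int, str, str]]  # (pos, ref base, consensus base)
    short_read_count: int
    long_read_count: int

    @property
    def resolved(self) -> bool:
        return not self.consensus_mismatches and not any(
            p.blocking for p in self.problems
        )


def remap_and_verify(
    edited: Sequence[ReferenceSeq],
    short_sets: dict[str, ReadSet],
    long_sets: Optional[dict[str, ReadSet]] = None,
    tie_ratio: float = 0.75,
    min_depth: int = 3,
    min_hp_len: int = DEFAULT_MIN_HP_LEN,
    mapper: Callable = map_reads,
) -> dict[str, VerificationReport]:
    """Remap the frozen per-haplotype read partitions against edited
    references and re-run problem detection.

    Positions where the re-mapped consensus disagrees with the edited
    reference (e.g. a wrong manual edit) are reported as consensus
    mismatches; an unedited reference reproduces the original problem
    report."""
    expected = sorted(short_sets)
    got = sorted(r.id for r in edited)
    if got != expected:
        raise ValueError(
            f"haplotype id mismatch: expected {expected}, got {got}"
        )
    out: dict[str, VerificationReport] = {}
    for ref in edited:
        short_set = short_sets[ref.id]
        n_long = len(long_sets[ref.id]) if long_sets and ref.id in long_sets else 0
        alignments = mapper(short_set, ref)
        pile = build_pileup(alignments, len(ref.bases))
        result = call_consensus(pile, tie_ratio=tie_ratio, min_depth=min_depth)
        problems = _mapping_problems(pile, result)
        problems.extend(homopolymer_check(alignments, ref, min_hp_len).problems())
        # compare the fresh majority call with the edited reference column
        # by column (IUPAC ambiguity is already reported as a problem above)
        mismatches = []
        counts = pile.counts
        depth = pile.depth
        major = counts[:, :4].argmax(axis=1)
        from .align import CODE_BASE

        for p in range(pile.ref_length):
            if depth[p] < min_depth:
                continue
            if counts[p, 4] > counts[p, major[p]]:
                mismatches.append((p, ref.bases[p], "-"))
            elif CODE_BASE[major[p]] != ref.bases[p]:
                mismatches.append((p, ref.bases[p], CODE_BASE[major[p]]))
        for p, ins in result.spliced_insertions:
            mismatches.append((p, "-", ins))
        mismatches.sort(key=lambda t: t[0])
        out[ref.id] = VerificationReport(
            haplotype_id=ref.id,
            problems=problems,
            consensus_mismatches=mismatches,
            short_read_count=len(short_set),
            long_read_count=n_long,
        )
    return out


@dataclass
class GappedSeq:
    """A row of a gapped multi-sequence alignment."""

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


def haplotype_alignment(refs: Sequence[ReferenceSeq]) -> list[GappedSeq]:
    """Gapped alignment of the haplotype consensus sequences for manual
    editing (center-star merge anchored on the first haplotype)."""
    import edlib

    refs = list(refs)
    if len(refs) == 1:
        return [GappedSeq(refs[0].id, refs[0].bases)]
    anchor = refs[0].bases
    L = len(anchor)
    # pairwise alignments to the anchor, as gapped (anchor, haplotype) rows
    pair_aln = []
    for other in refs[1:]:
        res = edlib.align(other.bases, anchor, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, other.bases, anchor)
        pair_aln.append((nice["target_aligned"], nice["query_aligned"]))

    def insertion_profile(tgt: str, qry: str):
        """Inserted haplotype bases before each anchor column (index L =
        after the last column)."""
        chunks: dict[int, str] = {}
        apos = 0
        pending: list[str] = []
        for ch, qc in zip(tgt, qry):
            if ch == "-":
                pending.append(qc)
            else:
                if pending:
                    chunks[apos] = "".join(pending)
                    pending = []
                apos += 1
        if pending:
            chunks[L] = "".join(pending)
        return chunks

    def column_bases(tgt: str, qry: str) -> list[str]:
        return [qc for ch, qc in zip(tgt, qry) if ch != "-"]

    profiles = [insertion_profile(t, q) for t, q in pair_aln]
    ins_len = np.zeros(L + 1, dtype=int)
    for prof in profiles:
        for p, chunk in prof.items():
            ins_len[p] = max(ins_len[p], len(chunk))

    def build_row(columns: list[str], prof: dict[int, str]) -> str:
        out = []
        for p in range(L + 1):
            if ins_len[p]:
                out.append(prof.get(p, "").ljust(int(ins_len[p]), "-"))
            if p < L:
                out.append(columns[p])
        return "".join(out)

    rows = [GappedSeq(refs[0].id, build_row(list(anchor), {}))]
    for ref, (tgt, qry), prof in zip(refs[1:], pair_aln, profiles):
        rows.append(GappedSeq(ref.id, build_row(column_bases(tgt, qry), prof)))
    return rows
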