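"""Majority-rule consensus calling and iterative draft refinement.

A consensus is always called from the pileup's consensus matrix: per column
the majority base is emitted; when the runner-up base is frequent enough the
two-base IUPAC ambiguity code is emitted and recorded; deletion-majority
columns are dropped (outputs are ungapped references; the report preserves
the original coordinates); high-frequency insertions are spliced in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import edlib
import numpy as np

from .align import CODE_BASE, Pileup, map_reads
from .seqio import ReadSet, ReferenceSeq

#: Two-base IUPAC ambiguity codes.
IUPAC2 = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

#: Runner-up must reach (1 - tie_ratio) of column depth to trigger an IUPAC
#: call; at long-read accuracies around 85% a 25% cut-off separates genuine
#: residual heterozygosity from sequencing noise.
DEFAULT_TIE_RATIO = 0.75

#: Columns below this depth are uncallable and emitted as N.
DEFAULT_MIN_DEPTH = 3


@dataclass
class ConsensusResult:
    """Outcome of a consensus call.

    ``sequence`` is the ungapped consensus (possibly containing IUPAC codes
    and N). Position lists refer to the *input reference* coordinates of the
    pileup, before deletion-majority columns were dropped.
    """

    sequence: str
    ambiguous_positions: list[tuple[int, str, dict]] = field(default_factory=list)
    dropped_positions: list[int] = field(default_factory=list)
    low_depth_positions: list[int] = field(default_factory=list)
    spliced_insertions: list[tuple[int, str]] = field(default_factory=list)
    conflicting_insertions: list[tuple[int, dict]] = field(default_factory=list)

    def as_reference(self, name: str) -> ReferenceSeq:
        return ReferenceSeq(name, self.sequence)


def call_consensus(
    pileup: Pileup,
    tie_ratio: float = DEFAULT_TIE_RATIO,
    min_depth: int = DEFAULT_MIN_DEPTH,
    emit_ambiguity: bool = True,
    no_indel: Optional[np.ndarray] = None,
) -> ConsensusResult:
    """Call a majority-rule consensus from a pileup / consensus matrix.

    Per column: emit the majority base; if the runner-up base frequency is at
    least ``1 - tie_ratio`` of the column depth, emit the IUPAC code of the
    top-two set and record the ambiguity; deletion-majority columns are
    dropped; columns below ``min_depth`` are called N. Insertions observed in
    more than half of the local depth are spliced in after their left-flanking
    position (only a single dominant inserted sequence is spliced; conflicting
    insertion alleles are reported instead).

    With ``emit_ambiguity=False`` the plain majority base is always emitted;
    ambiguities are still recorded. Mapping references (sample-specific
    reference, per-iteration drafts) are called this way so they stay on the
    plain {A, C, G, T, N} alphabet; only final polished sequences carry IUPAC
    codes.

    ``no_indel`` (boolean mask over positions) protects positions whose
    length was settled elsewhere — e.g. homopolymer runs resolved by the
    run-length resolver: there the majority *base* is still called, but
    deletion-majority dropping and insertion splicing are suppressed (the
    signals remain visible in the pileup for problem reporting).
    """
    if not 0.5 <= tie_ratio <= 1.0:
        raise ValueError("tie_ratio must be in [0.5, 1]")
    counts = pileup.counts
    if counts.sum() == 0:
        raise ValueError("no coverage: cannot call a consensus from an empty matrix")
    depth = counts.sum(axis=1)
    base_counts = counts[:, :4]
    top = np.argsort(base_counts, axis=1)  # ascending
    major = top[:, 3]
    runner = top[:, 2]

    result = ConsensusResult(sequence="")
    out: list[str] = []
    for p in range(pileup.ref_length):
        d = int(depth[p])
        protected = no_indel is not None and bool(no_indel[p])
        ins_here: Optional[str] = None
        if p in pileup.insertions and d > 0 and not protected:
            ctr = pileup.insertions[p]
            total_ins = sum(ctr.values())
            if total_ins > 0.5 * d:
                # the insertion event is majority-supported; its sequence is
                # the majority allele among the insertion-carrying reads
                seq, n_top = ctr.most_common(1)[0]
                if n_top > 0.5 * total_ins:
                    ins_here = seq
                else:
                    result.conflicting_insertions.append((p, dict(ctr)))
        if d < min_depth:
            out.append("N")
            result.low_depth_positions.append(p)
        else:
            dcount = int(counts[p, 4])
            mj, rn = int(major[p]), int(runner[p])
            if dcount > base_counts[p, mj] and not protected:
                result.dropped_positions.append(p)
            else:
                b1 = CODE_BASE[mj]
                if base_counts[p, rn] >= (1.0 - tie_ratio) * d and base_counts[p, rn] > 0:
                    code = IUPAC2[frozenset((b1, CODE_BASE[rn]))]
                    freqs = {
                        CODE_BASE[k]: float(base_counts[p, k]) / d for k in range(4)
                    }
                    result.ambiguous_positions.append((p, code, freqs))
                    out.append(code if emit_ambiguity else b1)
                else:
                    out.append(b1)
        if ins_here is not None:
            # splice the dominant inserted sequence (the majority allele
            # among observed insertion sequences at this junction)
            out.append(ins_here)
            result.spliced_insertions.append((p, ins_here))
    result.sequence = "".join(out)
    return result


@dataclass
class MapIterResult:
    consensus: ConsensusResult
    reference: ReferenceSeq
    changed_per_iteration: list[int]
    n_iterations: int


def map_iter(
    longreads: ReadSet,
    seed_consensus: ReferenceSeq,
    n_iter: int = 2,
    tie_ratio: float = DEFAULT_TIE_RATIO,
    min_depth: int = DEFAULT_MIN_DEPTH,
    mapper: Callable = map_reads,
    artifact_writer: Optional[Callable[[int, ReferenceSeq], None]] = None,
) -> MapIterResult:
    """Iteratively refine a haplotype consensus with long reads.

    Iteration *k* maps all reads to the consensus of iteration *k - 1* and
    calls a new consensus; two iterations are generally sufficient for long
    reads to converge. Stops early once an iteration changes zero positions.
    ``changed_per_iteration`` reports the edit distance between successive
    consensus sequences.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(longreads) == 0:
        raise ValueError("cannot refine a consensus without long reads")
    current = seed_consensus
    changed: list[int] = []
    last: Optional[ConsensusResult] = None
    for k in range(1, n_iter + 1):
        alignments = mapper(longreads, current)
        from .align import build_pileup

        pile = build_pileup(alignments, len(current.bases))
        res = call_consensus(
            pile, tie_ratio=tie_ratio, min_depth=min_depth, emit_ambiguity=False
        )
        if len(res.sequence) == 0:
            raise ValueError("consensus collapsed to length 0 during iteration")
        n_changed = edlib.align(res.sequence, current.bases, mode="NW")["editDistance"]
        changed.append(int(n_changed))
        current = ReferenceSeq(f"{seed_consensus.id}.iter{k}", res.sequence)
        last = res
        if artifact_writer is not None:
            artifact_writer(k, current)
        if n_changed == 0:
            break
    assert last is not None
    return MapIterResult(
        consensus=last,
        reference=ReferenceSeq(seed_consensus.id, last.sequence),
        changed_per_iteration=changed,
        n_iterations=len(changed),
    )
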