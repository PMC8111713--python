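"""Read-to-reference alignment and pileups.

Two aligners are exposed:

* :func:`map_reads` — the production mapper used by the pipeline. It wraps
  edlib's bit-parallel edit-distance alignment (infix mode: the read is
  aligned globally, reference overhangs are free), converting the alignment
  path into the internal edit-operation list. This plays the role an external
  mapper (bwa/minimap2) plays in a cluster deployment, while keeping the
  pipeline self-contained.
* :func:`semiglobal_align` — a banded affine-gap semi-global aligner with
  deterministic tie-breaking, suitable for small instances and as a reference
  implementation; it is validated against an unbanded dynamic-programming
  oracle in the test suite. It is not optimised for kilobase-scale mapping.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .seqio import LONG, Read, ReadSet, ReferenceSeq, revcomp

BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASE = "ACGT-"
DEL_CODE = 4

#: byte-value -> base code lookup; N and other ambiguity codes map to -1
_ENC = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_CODE.items():
    _ENC[ord(_b)] = _c
    _ENC[ord(_b.lower())] = _c


def encode_bases(bases: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0 C=1 G=2 T=3, anything else -1)."""
    return _ENC[np.frombuffer(bases.encode(), dtype=np.uint8)]


@dataclass
class AlignedRead:
    """A read with an alignment to a reference.

    ``ops`` is a list of ``(kind, length, inserted_bases)`` tuples with kind in
    {"match", "mismatch", "ins", "del"}; ``inserted_bases`` is a string iff
    kind == "ins", else None. ``ref_offset`` is 0-based.
    """

    read: Read
    ref_offset: int
    ops: list[tuple] = field(default_factory=list)
    score: float = 0.0
    reverse: bool = False
    #: index of the first aligned base in the (oriented) read — nonzero when
    #: leading bases are soft-clipped
    query_start: int = 0

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(l for k, l, _ in self.ops if k in ("match", "mismatch", "del"))

    @property
    def ref_end(self) -> int:
        return self.ref_offset + self.ref_span

    def aligned_bases(self) -> str:
        """The read bases as aligned (reverse-complemented if on the minus
        strand), i.e. the sequence the ops walk through."""
        return revcomp(self.read.bases) if self.reverse else self.read.bases

    def column_codes(self) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
        """Flatten the ops into per-reference-position base codes.

        Returns ``(positions, codes, insertions)`` where codes are 0-3 for
        bases, 4 for deletion, -1 for N (excluded from tallies by callers),
        and insertions is a list of ``(left_flanking_position, sequence)``.
        """
        qseq = encode_bases(self.aligned_bases())
        pos_chunks: list[np.ndarray] = []
        code_chunks: list[np.ndarray] = []
        insertions: list[tuple[int, str]] = []
        rpos = self.ref_offset
        qpos = self.query_start
        for kind, length, ins_seq in self.ops:
            if kind in ("match", "mismatch"):
                pos_chunks.append(np.arange(rpos, rpos + length))
                code_chunks.append(qseq[qpos : qpos + length])
                rpos += length
                qpos += length
            elif kind == "del":
                pos_chunks.append(np.arange(rpos, rpos + length))
                code_chunks.append(np.full(length, DEL_CODE, dtype=np.int8))
                rpos += length
            elif kind == "ins":
                insertions.append((rpos - 1, ins_seq))
                qpos += length
            else:  # pragma: no cover - guarded upstream
                raise ValueError(f"unknown op kind {kind!r}")
        if pos_chunks:
            positions = np.concatenate(pos_chunks)
            codes = np.concatenate(code_chunks).astype(np.int8)
        else:
            positions = np.empty(0, dtype=np.int64)
            codes = np.empty(0, dtype=np.int8)
        return positions, codes, insertions

    def base_at(self, positions: Sequence[int]) -> np.ndarray:
        """Base code at the given reference positions (-2 = not covered)."""
        pos, codes, _ = self.column_codes()
        out = np.full(len(positions), -2, dtype=np.int8)
        if len(pos) == 0:
            return out
        lookup = np.full(int(pos.max()) - int(pos.min()) + 1, -2, dtype=np.int8)
        lookup[pos - pos.min()] = codes
        q = np.asarray(positions)
        inside = (q >= pos.min()) & (q <= pos.max())
        out[inside] = lookup[q[inside] - pos.min()]
        return out


class Pileup:
    """Per-position counts over {A, C, G, T, del} plus insertion records.

    ``counts`` is an ``(L, 5)`` integer array; ``insertions`` maps a 0-based
    left-flanking position to a Counter of observed inserted sequences.
    N bases are never counted.
    """

    def __init__(self, ref_length: int):
        self.ref_length = ref_length
        self.counts = np.zeros((ref_length, 5), dtype=np.int32)
        self.insertions: dict[int, Counter] = {}

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add(self, aln: AlignedRead) -> None:
        positions, codes, insertions = aln.column_codes()
        keep = codes >= 0
        np.add.at(self.counts, (positions[keep], codes[keep]), 1)
        for pos, seq in insertions:
            if 0 <= pos < self.ref_length:
                self.insertions.setdefault(pos, Counter())[seq] += 1


def build_pileup(alignments: Iterable[AlignedRead], ref_length: int) -> Pileup:
    """Accumulate alignments into a pileup. Empty input yields an all-zero
    pileup."""
    pile = Pileup(ref_length)
    for aln in alignments:
        if aln.ref_end > ref_length:
            raise ValueError(
                f"alignment of {aln.read.id!r} ends at {aln.ref_end}, "
                f"beyond reference length {ref_length}"
            )
        pile.add(aln)
    return pile


# ---------------------------------------------------------------------------
# Production mapper (edlib)
# ---------------------------------------------------------------------------


def _cigar_to_ops(cigar: str, qseq: str) -> list[tuple]:
    ops: list[tuple] = []
    qpos = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "=":
            ops.append(("match", length, None))
            qpos += length
        elif ch == "X":
            ops.append(("mismatch", length, None))
            qpos += length
        elif ch == "I":
            ops.append(("ins", length, qseq[qpos : qpos + length]))
            qpos += length
        elif ch == "D":
            ops.append(("del", length, None))
        else:  # pragma: no cover
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return ops


#: Soft-trim scoring: per aligned column, matches reward +1 and every
#: edited column costs 2. Read tails whose running score is negative (e.g.
#: an overhang forced across a structural-deletion junction) are clipped,
#: emulating the soft-clipping a local mapper such as bwa mem applies.
TRIM_MATCH = 1
TRIM_PENALTY = -2


def soft_trim(
    aln: AlignedRead, match_score: int = TRIM_MATCH, penalty: int = TRIM_PENALTY
) -> AlignedRead:
    """Clip the alignment to its maximal-scoring contiguous segment.

    Edlib aligns the full query; a read tail that extends past a structural
    breakpoint gets forced into a mismatch run a local mapper would
    soft-clip. Scoring each aligned column (+1 match, -2 otherwise) and
    keeping the maximum-sum segment removes such tails while leaving genuine
    internal indels (paid for by long matching flanks) intact. Clipped bases
    simply drop out of the op list, so they never enter pileups.
    """
    if not aln.ops:
        return aln
    if len(aln.ops) == 1 and aln.ops[0][0] == "match":
        return aln
    lengths = np.array([l for _, l, _ in aln.ops])
    is_match = np.array([k == "match" for k, _, _ in aln.ops])
    scores = np.repeat(np.where(is_match, match_score, penalty), lengths)
    n = len(scores)
    # maximal-sum subarray via prefix sums
    prefix = np.concatenate(([0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return aln
    best_e = end + 1
    best_s = int(np.argmin(prefix[: end + 1]))
    if best_s == 0 and best_e == n:
        return aln
    ops: list[tuple] = []
    ref_consumed = 0
    query_consumed = 0
    u = 0
    for kind, length, ins_seq in aln.ops:
        lo, hi = u, u + length
        u = hi
        pre = min(max(best_s - lo, 0), length)
        keep = min(hi, best_e) - max(lo, best_s)
        if pre:
            if kind != "ins":
                ref_consumed += pre
            if kind != "del":
                query_consumed += pre
        if keep > 0:
            if kind == "ins":
                ops.append(("ins", keep, ins_seq[pre : pre + keep]))
            else:
                ops.append((kind, keep, None))
    # a kept segment must not start or end with a gap
    while ops and ops[0][0] in ("del", "ins"):
        kind, length, _ = ops.pop(0)
        if kind == "del":
            ref_consumed += length
        else:
            query_consumed += length
    while ops and ops[-1][0] in ("del", "ins"):
        ops.pop()
    return AlignedRead(
        read=aln.read,
        ref_offset=aln.ref_offset + ref_consumed,
        ops=ops,
        score=aln.score,
        reverse=aln.reverse,
        query_start=aln.query_start + query_consumed,
    )


def map_read(
    read: Read, ref: ReferenceSeq, try_rc: bool = True, trim: bool = True
) -> AlignedRead:
    """Align one read to the reference with edlib (infix mode).

    Both orientations are tried and the lower-edit-distance one kept; the
    score reported is the alignment identity in [0, 1]. With ``trim`` the
    ends are soft-clipped to the maximal-scoring segment (see
    :func:`soft_trim`).
    """
    # N is unknown, not a mismatch: an uncalled reference position must not
    # repel the very reads that could resolve it
    n_free = [("N", b) for b in "ACGT"]
    fwd = edlib.align(read.bases, ref.bases, mode="HW", task="distance",
                      additionalEqualities=n_free)
    best_seq, reverse, best_d = read.bases, False, fwd["editDistance"]
    # a forward alignment already well under the error rate of a true match
    # cannot be beaten by the reverse orientation
    if try_rc and best_d > 0.3 * len(read.bases):
        rc = revcomp(read.bases)
        rev = edlib.align(rc, ref.bases, mode="HW", task="distance",
                          additionalEqualities=n_free)
        if rev["editDistance"] < best_d:
            best_seq, reverse, best_d = rc, True, rev["editDistance"]
    res = edlib.align(best_seq, ref.bases, mode="HW", task="path",
                      additionalEqualities=n_free)
    start = res["locations"][0][0]
    ops = _cigar_to_ops(res["cigar"], best_seq)
    identity = 1.0 - res["editDistance"] / max(len(read), 1)
    aln = AlignedRead(read=read, ref_offset=start, ops=ops, score=identity, reverse=reverse)
    return soft_trim(aln) if trim else aln


def map_reads(
    reads: Iterable[Read], ref: ReferenceSeq, try_rc: bool = True, trim: bool = True
) -> list[AlignedRead]:
    """Map a collection of reads to a reference (see :func:`map_read`)."""
    return [map_read(r, ref, try_rc=try_rc, trim=trim) for r in reads]


# ---------------------------------------------------------------------------
# Built-in banded semi-global aligner
# ---------------------------------------------------------------------------

#: Default affine scoring (bwa-like baseline for amplicon reads).
MATCH = 2
MISMATCH = -4
GAP_OPEN = -4
GAP_EXTEND = -1

_NEG = -math.inf


def _semiglobal_score_matrixes(read, ref, band, scores):
    """DP over states M (diag), X (ins: read base vs gap), Y (del: ref base
    vs gap). Free end gaps on the read (reference overhangs unpenalised).
    Returns (H, back) where back holds packed traceback pointers."""
    match, mismatch, gap_open, gap_extend = scores
    m, n = len(read), len(ref)
    # band constraint: cell (i, j) valid iff |j - i| <= band (after global
    # offset handling, the read is assumed to start within `band` of the
    # reference start; with band >= n the search is exhaustive).
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)
    Y = np.full((m + 1, n + 1), _NEG)
    # ptr codes: 0 from M, 1 from X, 2 from Y, 3 start
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    for j in range(n + 1):
        M[0, j] = 0.0  # free leading reference overhang
        ptrM[0, j] = 3
    for i in range(1, m + 1):
        lo = max(0, i - band)
        hi = min(n, i + band)
        if i <= band:
            X[i, 0] = gap_open + gap_extend * i
            ptrX[i, 0] = 1 if i > 1 else 0
        for j in range(max(1, lo), hi + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            # diagonal predecessor, preference M > Y > X on ties
            cand = (M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
            best = max(cand)
            M[i, j] = best + s
            ptrM[i, j] = (0, 2, 1)[cand.index(best)]
            # X: consume read base against a gap (insertion)
            open_x = max(M[i - 1, j], Y[i - 1, j]) + gap_open + gap_extend
            ext_x = X[i - 1, j] + gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                ptrX[i, j] = 0 if M[i - 1, j] >= Y[i - 1, j] else 2
            else:
                X[i, j] = ext_x
                ptrX[i, j] = 1
            # Y: consume reference base against a gap (deletion)
            open_y = max(M[i, j - 1], X[i, j - 1]) + gap_open + gap_extend
            ext_y = Y[i, j - 1] + gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                ptrY[i, j] = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            else:
                Y[i, j] = ext_y
                ptrY[i, j] = 2
    return M, X, Y, ptrM, ptrX, ptrY


def _traceback(read, ref, M, X, Y, ptrM, ptrX, ptrY, end_j):
    m = len(read)
    i, j = m, end_j
    # choose terminal state: prefer match/mismatch over del over ins on ties
    states = {"M": M[i, j], "Y": Y[i, j], "X": X[i, j]}
    state = max(states, key=lambda k: (states[k], {"M": 2, "Y": 1, "X": 0}[k]))
    raw: list[tuple[str, Optional[str]]] = []
    while i > 0:
        if state == "M":
            kind = "match" if read[i - 1] == ref[j - 1] else "mismatch"
            raw.append((kind, None))
            prev = ptrM[i, j]
            i, j = i - 1, j - 1
            state = "MXY"[prev] if prev != 3 else "start"
            if state == "start":
                break
        elif state == "X":
            raw.append(("ins", read[i - 1]))
            prev = ptrX[i, j]
            i -= 1
            state = "MXY"[prev]
        else:  # Y
            raw.append(("del", None))
            prev = ptrY[i, j]
            j -= 1
            state = "MXY"[prev]
        if i == 0:
            break
    start_offset = j
    raw.reverse()
    # merge runs; attach inserted bases
    ops: list[tuple] = []
    for kind, base in raw:
        if ops and ops[0] is not None and ops[-1][0] == kind:
            prev_kind, prev_len, prev_seq = ops[-1]
            ops[-1] = (kind, prev_len + 1, (prev_seq + base) if base else None)
        else:
            ops.append((kind, 1, base if base else None))
    return start_offset, ops


def _semiglobal_one(bases: str, ref: ReferenceSeq, band: int, scores):
    M, X, Y, pM, pX, pY = _semiglobal_score_matrixes(bases, ref.bases, band, scores)
    m, n = len(bases), len(ref.bases)
    H_last = np.maximum(np.maximum(M[m], X[m]), Y[m])
    if not np.isfinite(H_last).any():
        raise ValueError(
            f"band {band} too small to connect alignment endpoints; "
            f"increase the band (read length {m}, reference length {n})"
        )
    end_j = int(np.argmax(H_last))
    score = float(H_last[end_j])
    offset, ops = _traceback(bases, ref.bases, M, X, Y, pM, pX, pY, end_j)
    return score, offset, ops


def semiglobal_align(
    read: Read,
    ref: ReferenceSeq,
    band: Optional[int] = None,
    scores: tuple = (MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND),
    try_rc: bool = True,
) -> AlignedRead:
    """Optimal banded semi-global alignment of a read to a reference.

    End gaps on the read (reference overhangs) are free; gaps use affine
    scoring ``open + k * extend``. Both orientations are tried when
    ``try_rc``. Ties break deterministically (match > mismatch > del > ins).
    With ``band >= len(ref)`` the search is exhaustive and equals an unbanded
    dynamic program. Insertions longer than the band are not representable;
    supply a SAM from an external mapper in that regime.
    """
    if not read.bases or not ref.bases:
        raise ValueError("read and reference must be non-empty")
    if band is None:
        band = len(ref.bases)
    fwd = _semiglobal_one(read.bases, ref, band, scores)
    best, reverse = fwd, False
    if try_rc:
        rev = _semiglobal_one(revcomp(read.bases), ref, band, scores)
        if rev[0] > fwd[0]:
            best, reverse = rev, True
    score, offset, ops = best
    return AlignedRead(read=read, ref_offset=offset, ops=ops, score=score, reverse=reverse)


# ---------------------------------------------------------------------------
# Coverage subsampling
# ---------------------------------------------------------------------------


def subsample_by_coverage(
    alignments: Sequence[AlignedRead], target_cov: int, seed: int
) -> list[AlignedRead]:
    """Greedy randomized coverage-based subsampling.

    Reads are visited in a seeded random order; a read is kept only while some
    reference position it spans is still below ``target_cov``. Sampling is by
    coverage, not read count, so long and short reads are treated fairly.
    Deterministic for a fixed seed.
    """
    if target_cov < 1:
        raise ValueError("target_cov must be >= 1")
    alignments = list(alignments)
    if not alignments:
        return []
    ref_length = max(a.ref_end for a in alignments)
    depth = np.zeros(ref_length, dtype=np.int32)
    order = np.random.default_rng(seed).permutation(len(alignments))
    kept_idx = []
    for idx in order:
        aln = alignments[idx]
        s, e = aln.ref_offset, aln.ref_end
        if (depth[s:e] < target_cov).any():
            depth[s:e] += 1
            kept_idx.append(idx)
    kept_idx.sort()
    return [alignments[i] for i in kept_idx]
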