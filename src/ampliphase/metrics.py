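"""Accuracy metrics for assembled haplotypes versus ground truth.

Assembled haplotypes are attributed to their target truth haplotype by
overall similarity. Differences to the target are then classified: a
variant whose allele matches the *alternative* truth haplotype at the
homologous position is part of a phase switch (runs of consecutive such
variants collapse into one switch error); any other difference is a
mismatch error. Rates are normalized by the number of positions at which
the target truth haplotype deviates from the generic reference — the
maximum number of possible errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .seqio import ReferenceSeq
from .simulate import GroundTruth


def identity(a: str, b: str) -> float:
    """Global alignment identity: 1 - edit distance / max length."""
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b), 1)


def attribute_haplotypes(
    assembled: Sequence[ReferenceSeq], truth: Sequence[ReferenceSeq]
) -> dict[str, str]:
    """Optimal assignment of assembled to truth haplotypes maximizing total
    pairwise alignment identity (exact over all pairings)."""
    if len(assembled) != len(truth):
        raise ValueError(
            f"{len(assembled)} assembled vs {len(truth)} truth haplotypes: "
            "counts must match for attribution"
        )
    n = len(assembled)
    sim = np.zeros((n, n))
    for i, a in enumerate(assembled):
        for j, t in enumerate(truth):
            sim[i, j] = identity(a.bases, t.bases)
    rows, cols = linear_sum_assignment(-sim)
    return {assembled[i].id: truth[j].id for i, j in zip(rows, cols)}


@dataclass
class VariantEvent:
    """A single difference between a query and a target sequence, in target
    coordinates. Substitutions are per-position events; each contiguous
    indel is one event."""

    pos: int
    kind: str  # "sub" | "ins" | "del"
    allele: str  # substituted base, inserted sequence, or deleted sequence


def _event_aligner():
    from Bio import Align

    # affine gap scores keep an indel as one contiguous event; unit-cost
    # alignment would scatter a kb-scale deletion across accidental matches
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-4,
        extend_gap_score=-0.5,
    )


_EVENT_ALIGNER = None


def diff_events(query: str, target: str) -> list[VariantEvent]:
    """Variant events of ``query`` relative to ``target`` under global
    affine-gap alignment, sorted by target position."""
    global _EVENT_ALIGNER
    if _EVENT_ALIGNER is None:
        _EVENT_ALIGNER = _event_aligner()
    aln = _EVENT_ALIGNER.align(target, query)[0]
    target_blocks, query_blocks = aln.aligned
    events: list[VariantEvent] = []
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if ts > prev_t:
            events.append(VariantEvent(prev_t, "del", target[prev_t:ts]))
        if qs > prev_q:
            events.append(VariantEvent(ts, "ins", query[prev_q:qs]))
        for k in range(te - ts):
            if target[ts + k] != query[qs + k]:
                events.append(VariantEvent(ts + k, "sub", query[qs + k]))
        prev_t, prev_q = te, qe
    if prev_t < len(target):
        events.append(VariantEvent(prev_t, "del", target[prev_t:]))
    if prev_q < len(query):
        events.append(VariantEvent(len(target), "ins", query[prev_q:]))
    return events


def _alt_profile(alt: str, target: str):
    """Where and how the alternative haplotype differs from the target:
    per-position substituted base, per-position deletion flags, and inserted
    sequences keyed by target position."""
    subs: dict[int, str] = {}
    deleted: set[int] = set()
    ins: dict[int, str] = {}
    for ev in diff_events(alt, target):
        if ev.kind == "sub":
            subs[ev.pos] = ev.allele
        elif ev.kind == "del":
            deleted.update(range(ev.pos, ev.pos + len(ev.allele)))
        else:
            ins[ev.pos] = ev.allele
    return subs, deleted, ins


def classify_differences(
    assembled: str, target: str, alt: str
) -> list[tuple[VariantEvent, str]]:
    """Classify each assembled-vs-target difference as "switch" (the allele
    matches the alternative truth haplotype at the homologous position) or
    "mismatch" (matches neither truth haplotype)."""
    subs, deleted, ins = _alt_profile(alt, target)
    out = []
    for ev in diff_events(assembled, target):
        if ev.kind == "sub":
            is_switch = subs.get(ev.pos) == ev.allele
        elif ev.kind == "del":
            span = range(ev.pos, ev.pos + len(ev.allele))
            is_switch = len(span) > 0 and all(p in deleted for p in span)
        else:
            is_switch = ins.get(ev.pos) == ev.allele
        out.append((ev, "switch" if is_switch else "mismatch"))
    return out


def count_errors(
    assembled: ReferenceSeq,
    target_truth: ReferenceSeq,
    alt_truth: ReferenceSeq,
    generic: ReferenceSeq,
) -> tuple[int, int, int]:
    """Mismatch errors, phase-switch errors and the deviating-position
    denominator for one assembled haplotype.

    Consecutive switch-classified differences with no intervening mismatch
    collapse into a single switch error (a switch is a single variant or a
    run of consecutive variants attributable to the alternative haplotype).
    ``deviating_positions`` counts the differences between the target truth
    haplotype and the generic reference the same way (substitutions
    per-position, one event per indel).
    """
    if identity(assembled.bases, target_truth.bases) < 0.5:
        raise ValueError(
            "assembled/target identity below 50%: attribution likely wrong"
        )
    classified = classify_differences(
        assembled.bases, target_truth.bases, alt_truth.bases
    )
    mismatch = sum(1 for _, c in classified if c == "mismatch")
    switch = 0
    in_run = False
    for _, c in classified:  # events come sorted by target position
        if c == "switch":
            if not in_run:
                switch += 1
                in_run = True
        else:
            in_run = False
    deviating = len(diff_events(target_truth.bases, generic.bases))
    return mismatch, switch, deviating


@dataclass
class ErrorReport:
    """Per-haplotype error counts and rates for one sample/locus unit."""

    table: pd.DataFrame
    attribution: dict[str, str]

    @property
    def mean_mismatch_rate(self) -> float:
        return float(self.table["mismatch_rate"].mean())

    @property
    def mean_switch_rate(self) -> float:
        return float(self.table["switch_rate"].mean())

    @property
    def total_switch_errors(self) -> int:
        return int(self.table["switch_errors"].sum())

    @property
    def total_mismatch_errors(self) -> int:
        return int(self.table["mismatch_errors"].sum())


def score_assembly(
    assembled: Sequence[ReferenceSeq], truth: GroundTruth
) -> ErrorReport:
    """Attribute assembled haplotypes to truth and compute error rates.

    Rates are errors divided by the deviating-position count of the target
    truth haplotype versus the generic reference; haplotypes whose truth
    equals the generic reference are excluded (rates undefined) with a
    warning.
    """
    import warnings

    mapping = attribute_haplotypes(assembled, truth.haplotypes)
    truth_by_id = {h.id: h for h in truth.haplotypes}
    rows = []
    for asm in assembled:
        target = truth_by_id[mapping[asm.id]]
        others = [h for h in truth.haplotypes if h.id != target.id]
        # the alternative is the most similar other truth haplotype
        alt = max(others, key=lambda h: identity(asm.bases, h.bases)) if others else target
        mismatch, switch, deviating = count_errors(
            asm, target, alt, truth.generic_reference
        )
        if deviating == 0:
            warnings.warn(
                f"{target.id}: truth equals the generic reference; "
                "rates undefined, unit excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "assembled": asm.id,
                "truth": target.id,
                "exact": asm.bases == target.bases,
                "identity": identity(asm.bases, target.bases),
                "mismatch_errors": mismatch,
                "switch_errors": switch,
                "deviating_positions": deviating,
                "mismatch_rate": mismatch / deviating,
                "switch_rate": switch / deviating,
            }
        )
    return ErrorReport(table=pd.DataFrame(rows), attribution=mapping)


def mean_rates(reports: Sequence[ErrorReport]) -> dict[str, float]:
    """Unweighted means across sample x gene units."""
    return {
        "mismatch_rate": float(np.mean([r.mean_mismatch_rate for r in reports])),
        "switch_rate": float(np.mean([r.mean_switch_rate for r in reports])),
    }


def reduction(rate_ref: float, rate_other: float) -> float:
    """Percent reduction of ``rate_ref`` relative to ``rate_other``:
    100 * (rate_other - rate_ref) / rate_other, to 2 decimals, half-up."""
    if rate_other == 0:
        raise ValueError(
            "reduction undefined for a zero comparison rate"
            + ("" if rate_ref == 0 else " with a nonzero reference rate")
        )
    value = 100.0 * (rate_other - rate_ref) / rate_other
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
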