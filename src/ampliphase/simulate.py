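"""Ground-truth simulation for offline validation.

Generates a random generic reference for a polymorphic locus, derives two
(or more) haplotypes from it (SNVs, kb-scale indels, homopolymer-length
differences), and simulates platform-realistic reads: accurate ~300 bp
short reads at high depth (fragmented amplicon, flat coverage across the
locus) and full-length long reads at ~85% accuracy with platform-specific
substitution/insertion/deletion ratios. PCR chimeras can be injected with
their identities recorded so downstream pruning can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import LONG, SHORT, Read, ReadSet, ReferenceSeq

#: Long-read substitution/insertion/deletion ratios per platform.
PACBIO_RATIO = (6, 50, 54)
ONT_RATIO = (23, 31, 46)

#: Long-read mean accuracy.
DEFAULT_ACCURACY = 0.85

#: Short-read per-base substitution rate (Illumina-like).
DEFAULT_SHORT_ERR = 0.002

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class IndelSpec:
    """A structural indel carried by one haplotype (position auto-placed
    when None)."""

    hap: int
    length: int
    kind: str  # "ins" | "del"
    position: Optional[int] = None


@dataclass
class HomopolymerSpec:
    """A homopolymer tract with per-haplotype lengths; the generic reference
    carries the first haplotype's length."""

    lengths: tuple
    base: Optional[str] = None
    position: Optional[int] = None


@dataclass
class SimConfig:
    """Study conditions for the end-to-end validation scenario.

    Defaults describe a heterozygous 5 kb amplicon: two haplotypes separated
    by 10 SNVs, one 50 bp deletion and a homopolymer tract differing by one
    unit; short reads at 500x total depth with low substitution error; 60
    full-length long reads at 85% accuracy with ONT-like error composition.
    """

    seed: int = 0
    ref_length: int = 5000
    n_haplotypes: int = 2
    n_snv: int = 10
    indels: list = field(default_factory=lambda: [IndelSpec(hap=1, length=50, kind="del")])
    homopolymers: list = field(default_factory=lambda: [HomopolymerSpec(lengths=(12, 13))])
    short_depth: int = 500
    short_read_len: int = 300
    short_err: float = DEFAULT_SHORT_ERR
    long_depth: int = 60
    long_accuracy: float = DEFAULT_ACCURACY
    long_ratio: tuple = ONT_RATIO
    chimera_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.long_accuracy <= 1:
            raise ValueError("accuracy must be in (0, 1]")
        if any(r <= 0 for r in self.long_ratio):
            raise ValueError("sub/ins/del ratio components must be positive")


@dataclass
class VariantRecord:
    hap: str
    ref_pos: int
    ref_allele: str
    alt_allele: str
    type: str  # "snv" | "ins" | "del"


@dataclass
class GroundTruth:
    """Simulated truth: generic reference, haplotypes, and the variant table
    whose application to the generic reference reproduces each haplotype."""

    generic_reference: ReferenceSeq
    haplotypes: list[ReferenceSeq]
    variant_table: dict[str, list[VariantRecord]]
    snv_positions: list[int] = field(default_factory=list)
    homopolymer_runs: list = field(default_factory=list)  # (pos, base, lengths)
    chimera_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "generic_reference": self.generic_reference.id,
            "haplotypes": [h.id for h in self.haplotypes],
            "snv_positions": self.snv_positions,
            "homopolymer_runs": [
                {"position": p, "base": b, "lengths": list(ls)}
                for p, b, ls in self.homopolymer_runs
            ],
            "variants": {
                h: [v.__dict__ for v in recs] for h, recs in self.variant_table.items()
            },
            "chimera_ids": self.chimera_ids,
        }
        with open(path, "wt") as out:
            json.dump(payload, out, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write("hap\tref_pos\tref_allele\talt_allele\ttype\n")
            for recs in self.variant_table.values():
                for v in recs:
                    out.write(
                        f"{v.hap}\t{v.ref_pos}\t{v.ref_allele or '-'}\t"
                        f"{v.alt_allele or '-'}\t{v.type}\n"
                    )


def apply_variant_table(generic: ReferenceSeq, records: Sequence[VariantRecord]) -> str:
    """Apply variant records (positions refer to the generic reference) from
    right to left; reconstructs the haplotype byte-for-byte."""
    seq = generic.bases
    for v in sorted(records, key=lambda r: r.ref_pos, reverse=True):
        p = v.ref_pos
        assert seq[p : p + len(v.ref_allele)] == v.ref_allele, (
            f"variant table inconsistent at {p}"
        )
        seq = seq[:p] + v.alt_allele + seq[p + len(v.ref_allele) :]
    return seq


def _place_features(rng, ref_length, features_len, end_margin, spacing, occupied):
    """Pick a start for a feature of the given length, keeping away from the
    amplicon termini (``end_margin``) and other features (``spacing``)."""
    if ref_length - end_margin - features_len <= end_margin:
        raise ValueError("too many variants for the reference length")
    for _ in range(10_000):
        pos = int(rng.integers(end_margin, ref_length - end_margin - features_len))
        if all(
            pos + features_len + spacing <= s or pos >= e + spacing
            for s, e in occupied
        ):
            occupied.append((pos, pos + features_len))
            return pos
    raise ValueError("too many variants for the reference length")


def simulate_haplotypes(cfg: SimConfig) -> GroundTruth:
    """Generate a random generic reference and derive the haplotypes.

    SNVs are assigned round-robin: SNV *i* places an alternative base on
    haplotype ``i % n_haplotypes``, so every pair of haplotypes differs at
    every SNV and each haplotype also deviates from the generic reference at
    a share of them (giving every haplotype a non-empty truth-vs-generic
    difference set, the denominator of the error rates).
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = cfg.n_haplotypes
    L = cfg.ref_length
    codes = rng.integers(0, 4, size=L)

    occupied: list[tuple[int, int]] = []
    feature_margin = 120
    end_margin = max(cfg.short_read_len, 300)

    # homopolymer tracts are embedded in the generic reference at the first
    # haplotype's length, flanked by non-run bases
    hp_runs = []
    for spec in cfg.homopolymers:
        base = spec.base or "ACGT"[rng.integers(0, 4)]
        run_len = int(spec.lengths[0])
        pos = (
            spec.position
            if spec.position is not None
            else _place_features(rng, L, run_len, end_margin, feature_margin, occupied)
        )
        b = "ACGT".index(base)
        codes[pos : pos + run_len] = b
        for flank in (pos - 1, pos + run_len):
            if codes[flank] == b:
                codes[flank] = (b + 1 + rng.integers(0, 3)) % 4
        hp_runs.append((pos, base, tuple(int(x) for x in spec.lengths)))

    indel_pos = []
    for spec in cfg.indels:
        pos = (
            spec.position
            if spec.position is not None
            else _place_features(rng, L, spec.length, end_margin, feature_margin, occupied)
        )
        indel_pos.append(pos)

    generic = ReferenceSeq("generic_ref", _decode(codes))

    # SNV placement outside reserved intervals; a margin of 30 bp keeps
    # point variants clear of indel/homopolymer junctions where local
    # alignment is intrinsically ambiguous
    snv_positions: list[int] = []
    guard = [(s - 30, e + 30) for s, e in occupied]
    for _ in range(cfg.n_snv):
        for _try in range(10_000):
            p = int(rng.integers(end_margin, L - end_margin))
            if all(not (s <= p < e) for s, e in guard) and all(
                abs(p - q) > 3 for q in snv_positions
            ):
                snv_positions.append(p)
                break
        else:
            raise ValueError("too many variants for the reference length")
    snv_positions.sort()

    hap_names = [f"hap_{chr(ord('A') + i)}" for i in range(n_hap)]
    table: dict[str, list[VariantRecord]] = {h: [] for h in hap_names}

    for i, p in enumerate(snv_positions):
        carrier = hap_names[i % n_hap]
        ref_base = generic.bases[p]
        alt = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
        table[carrier].append(VariantRecord(carrier, p, ref_base, alt, "snv"))

    for spec, pos in zip(cfg.indels, indel_pos):
        hap = hap_names[spec.hap]
        if spec.kind == "del":
            table[hap].append(
                VariantRecord(hap, pos, generic.bases[pos : pos + spec.length], "", "del")
            )
        elif spec.kind == "ins":
            ins = _decode(rng.integers(0, 4, size=spec.length))
            table[hap].append(VariantRecord(hap, pos, "", ins, "ins"))
        else:
            raise ValueError(f"unknown indel kind {spec.kind!r}")

    for pos, base, lengths in hp_runs:
        ref_len = lengths[0]
        for h_idx, h_len in enumerate(lengths[:n_hap]):
            hap = hap_names[h_idx]
            delta = int(h_len) - ref_len
            end = pos + ref_len
            if delta > 0:
                table[hap].append(VariantRecord(hap, end, "", base * delta, "ins"))
            elif delta < 0:
                table[hap].append(
                    VariantRecord(hap, end + delta, generic.bases[end + delta : end], "", "del")
                )

    haplotypes = [
        ReferenceSeq(h, apply_variant_table(generic, table[h])) for h in hap_names
    ]
    return GroundTruth(
        generic_reference=generic,
        haplotypes=haplotypes,
        variant_table=table,
        snv_positions=snv_positions,
        homopolymer_runs=hp_runs,
    )


def simulate_short_reads(
    h: ReferenceSeq,
    depth: int = 2000,
    read_len: int = 300,
    err: float = DEFAULT_SHORT_ERR,
    seed: int = 0,
    min_len: int = 30,
) -> ReadSet:
    """Fragmented-amplicon short reads with per-base substitution errors.

    Fragment starts are uniform over ``[-(read_len - 1), L - 1]`` and clipped
    to the amplicon, so coverage is flat across the locus including its
    termini; fragments shorter than ``min_len`` are discarded. Realized mean
    depth is within 10% of the target.
    """
    rng = np.random.default_rng(seed)
    L = len(h.bases)
    if read_len > L:
        raise ValueError("read_len exceeds haplotype length")
    n = int(round(depth * (L + read_len - 1) / read_len))
    starts = rng.integers(-(read_len - 1), L, size=n)
    codes = _encode(h.bases)
    reads = []
    for i, s in enumerate(starts):
        a, b = max(0, int(s)), min(L, int(s) + read_len)
        if b - a < min_len:
            continue
        frag = codes[a:b].copy()
        errs = np.nonzero(rng.random(b - a) < err)[0]
        if len(errs):
            frag[errs] = (frag[errs] + rng.integers(1, 4, size=len(errs))) % 4
        reads.append(Read(f"{h.id}_sr{i}", _decode(frag), "I" * (b - a), SHORT))
    return ReadSet(reads, SHORT)


def simulate_long_reads(
    h: ReferenceSeq,
    depth: int,
    accuracy: float = DEFAULT_ACCURACY,
    ratio: tuple = ONT_RATIO,
    seed: int = 0,
    op_counter: Optional[dict] = None,
) -> ReadSet:
    """Full-length amplicon long reads with a homogeneous per-base error
    rate ``1 - accuracy`` and error types drawn in the given
    substitution/insertion/deletion proportion. Since reads span the whole
    amplicon, ``depth`` equals the number of reads. ``op_counter`` (keys
    "sub"/"ins"/"del"), when given, accumulates the injected error counts
    so the realized composition can be audited."""
    rng = np.random.default_rng(seed)
    L = len(h.bases)
    probs = np.asarray(ratio, dtype=float)
    probs /= probs.sum()
    codes = _encode(h.bases)
    reads = []
    for i in range(depth):
        err_pos = np.nonzero(rng.random(L) < (1.0 - accuracy))[0]
        kinds = rng.choice(3, size=len(err_pos), p=probs)  # 0 sub, 1 ins, 2 del
        if op_counter is not None:
            for key, k in (("sub", 0), ("ins", 1), ("del", 2)):
                op_counter[key] = op_counter.get(key, 0) + int((kinds == k).sum())
        work = codes.copy()
        sub_pos = err_pos[kinds == 0]
        if len(sub_pos):
            work[sub_pos] = (work[sub_pos] + rng.integers(1, 4, size=len(sub_pos))) % 4
        rep = np.ones(L, dtype=np.int64)
        rep[err_pos[kinds == 2]] = 0
        ins_pos = err_pos[kinds == 1]
        rep[ins_pos] = 2
        out = np.repeat(work, rep)
        if len(ins_pos):
            out_start = np.cumsum(rep) - rep
            out[out_start[ins_pos] + 1] = rng.integers(0, 4, size=len(ins_pos))
        reads.append(Read(f"{h.id}_lr{i}", _decode(out), None, LONG))
    return ReadSet(reads, LONG)


def inject_chimeras(
    sets: dict[str, ReadSet], rate: float, seed: int = 0
) -> tuple[ReadSet, list[str]]:
    """Replace read pairs from different haplotypes with single PCR-chimera
    reads switching template at a random internal breakpoint.

    ``rate`` is the chimeric fraction of the output read set; chimera ids are
    returned so their downstream elimination can be audited. Rate 0 returns
    the pooled input unchanged.
    """
    if not 0 <= rate < 0.5:
        raise ValueError("chimera rate must be in [0, 0.5)")
    if len(sets) < 2 and rate > 0:
        raise ValueError("chimeras need at least two haplotype read sets")
    rng = np.random.default_rng(seed)
    pools = {h: list(rs.reads) for h, rs in sets.items()}
    total = sum(len(p) for p in pools.values())
    n_chim = int(round(rate * total))
    chimeras: list[Read] = []
    hap_ids = sorted(pools)
    for k in range(n_chim):
        donors = [h for h in hap_ids if pools[h]]
        if len(donors) < 2:
            break
        a, b = rng.choice(len(donors), size=2, replace=False)
        ha, hb = donors[int(a)], donors[int(b)]
        ra = pools[ha].pop(int(rng.integers(len(pools[ha]))))
        rb = pools[hb].pop(int(rng.integers(len(pools[hb]))))
        f = rng.uniform(0.1, 0.9)
        bases = ra.bases[: int(f * len(ra.bases))] + rb.bases[int(f * len(rb.bases)) :]
        chimeras.append(Read(f"chimera_{k}_{ha}_{hb}", bases, None, LONG))
    combined = [r for h in hap_ids for r in pools[h]] + chimeras
    return ReadSet(combined, LONG), [c.id for c in chimeras]


@dataclass
class SimulatedDataset:
    truth: GroundTruth
    short_reads: ReadSet
    long_reads: ReadSet


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Simulate the full study scenario: truth haplotypes plus pooled short
    and long read sets (depths split evenly across haplotypes), with
    chimeras injected at ``cfg.chimera_rate``."""
    truth = simulate_haplotypes(cfg)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * cfg.n_haplotypes + 1)
    short_all: list[Read] = []
    long_sets: dict[str, ReadSet] = {}
    for i, h in enumerate(truth.haplotypes):
        short_all.extend(
            simulate_short_reads(
                h,
                depth=cfg.short_depth // cfg.n_haplotypes,
                read_len=cfg.short_read_len,
                err=cfg.short_err,
                seed=int(seeds[2 * i]),
            ).reads
        )
        long_sets[h.id] = simulate_long_reads(
            h,
            depth=cfg.long_depth // cfg.n_haplotypes,
            accuracy=cfg.long_accuracy,
            ratio=cfg.long_ratio,
            seed=int(seeds[2 * i + 1]),
        )
    long_reads, chimera_ids = inject_chimeras(
        long_sets, cfg.chimera_rate, seed=int(seeds[-1])
    )
    truth.chimera_ids = chimera_ids
    return SimulatedDataset(
        truth=truth,
        short_reads=ReadSet(short_all, SHORT),
        long_reads=long_reads,
    )
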